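"""Reaction-network construction for the cartilage-breakdown model.

The model is assembled from three mass-action fragments:

* an IL-1 arm (IL-1/IL-1R -> IRAK-2 -> TRAF6 -> JNK & p38 -> phospho-c-Jun
  -> c-Jun homodimer, a weak transcription factor),
* an OSM arm (OSM/OSMR -> JAK-1 -> STAT-3 -> c-Fos; p38-phosphorylated
  c-Fos binds phospho-c-Jun to form AP-1, a strong transcription factor),
* an extracellular-matrix arm (proMMP activation, TIMP inhibition,
  ADAMTS-4 cleavage of the aggrecan-collagen complex, collagenolysis).

Every reaction is pure mass action: rate = k * prod(reactant amounts) *
prod(modifier amounts).  Amounts are molecule counts (compartment volumes
are all 1), time is seconds internally.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

HOUR = 3600.0

COMPARTMENTS = ("cytoplasm", "nucleus", "matrix")

ROLES = (
    "ligand", "receptor", "antagonist", "kinase", "phosphatase",
    "transcription_factor", "transcript", "protein", "proenzyme",
    "enzyme", "inhibitor", "matrix_component", "fragment", "complex",
)


@dataclass(frozen=True)
class SpeciesDef:
    """One chemical species: a molecule count in a named compartment."""

    id: str
    display_name: str
    compartment: str
    initial_amount: int
    role: str

    def __post_init__(self):
        if self.initial_amount < 0:
            raise ValueError(f"initial_amount of {self.id} must be >= 0")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r} for {self.id}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.id}")


@dataclass(frozen=True)
class RateParameter:
    id: str
    value: float
    units: str  # per_second | per_molecule_per_second
    description: str = ""

    def __post_init__(self):
        if self.value < 0:
            raise ValueError(f"parameter {self.id} must be non-negative")
        if self.units not in ("per_second", "per_molecule_per_second"):
            raise ValueError(f"bad units {self.units!r} for {self.id}")


@dataclass(frozen=True)
class ReactionDef:
    """Mass-action reaction.

    ``modifiers`` are catalytic species: they multiply the rate but are not
    consumed.  ``rate_constant`` names a :class:`RateParameter`.
    ``anchor`` is a free-text note on the biological motivation.
    """

    id: str
    reactants: dict
    products: dict
    modifiers: tuple
    rate_constant: str
    anchor: str = ""

    def __post_init__(self):
        for sto in list(self.reactants.values()) + list(self.products.values()):
            if not (isinstance(sto, int) and sto > 0):
                raise ValueError(f"stoichiometry in {self.id} must be a positive integer")

    @property
    def order(self) -> int:
        """Kinetic order: total reactant stoichiometry plus modifier count."""
        return sum(self.reactants.values()) + len(self.modifiers)

    def species_ids(self):
        out = set(self.reactants) | set(self.products) | set(self.modifiers)
        return out


@dataclass
class ModelFragment:
    """A self-contained submodel, open only at its interface species."""

    name: str
    species: list
    reactions: list
    parameters: list
    interface_species: list = field(default_factory=list)

    def species_ids(self):
        return {s.id for s in self.species}


class CompositionError(ValueError):
    pass


@dataclass
class ModelSpec:
    """The merged model: compartments, species, reactions, parameters."""

    name: str
    version: str
    compartments: tuple
    species: list
    reactions: list
    parameters: list
    conserved_pools: dict = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def species_index(self):
        return {s.id: i for i, s in enumerate(self.species)}

    def parameter_map(self):
        return {p.id: p for p in self.parameters}

    def species_map(self):
        return {s.id: s for s in self.species}

    def initial_state(self):
        import numpy as np

        return np.array([float(s.initial_amount) for s in self.species])

    def stoichiometry_matrix(self):
        """Net stoichiometry, shape (n_species, n_reactions)."""
        import numpy as np

        idx = self.species_index()
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for sid, sto in r.reactants.items():
                S[idx[sid], j] -= sto
            for sid, sto in r.products.items():
                S[idx[sid], j] += sto
        return S

    # -- derived copies --------------------------------------------------
    def with_parameters(self, overrides: dict) -> "ModelSpec":
        """Copy with parameter values replaced (absolute values, not scalings)."""
        pm = self.parameter_map()
        unknown = set(overrides) - set(pm)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        params = [
            replace(p, value=float(overrides[p.id])) if p.id in overrides else p
            for p in self.parameters
        ]
        return replace(self, parameters=params)

    def with_initial_amounts(self, overrides: dict) -> "ModelSpec":
        sm = self.species_map()
        unknown = set(overrides) - set(sm)
        if unknown:
            raise KeyError(f"unknown species: {sorted(unknown)}")
        species = [
            replace(s, initial_amount=int(round(overrides[s.id]))) if s.id in overrides else s
            for s in self.species
        ]
        return replace(self, species=species)

    def scaled_parameters(self, scalings: dict) -> "ModelSpec":
        pm = self.parameter_map()
        return self.with_parameters({k: pm[k].value * m for k, m in scalings.items()})

    def copy(self) -> "ModelSpec":
        return copy.deepcopy(self)

    def species_table(self):
        """Species summary as a pandas DataFrame (exportable as CSV)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "id": s.id,
                    "display_name": s.display_name,
                    "compartment": s.compartment,
                    "initial_amount": s.initial_amount,
                    "role": s.role,
                }
                for s in self.species
            ]
        )


# ---------------------------------------------------------------------------
# Baseline parameter values.
#
# Units: first-order and zeroth-order constants are per_second; constants of
# reactions with two concentration factors (reactants plus modifiers) are
# per_molecule_per_second.  k_phoscJun, k_phoscFos and k_phosSTAT3 carry the
# literature baseline values (1e-4, 5e-7 and 5e-3 molecules^-1 s^-1); the MMP
# removal constant encodes the ~30 h half-life of active MMP pools; MMP-1
# transcription runs at 10x the MMP-13 rate in both transcription-factor
# contexts, with one shared mRNA decay constant.
# ---------------------------------------------------------------------------

MMP_REMOVAL = math.log(2) / (30 * HOUR)        # 30 h active-MMP half-life

BASELINE_PARAMETERS = {
    # receptor layer
    "k_on_il1": (1e-4, "per_molecule_per_second", "IL-1 binding to IL-1R"),
    "k_off_il1": (1e-3, "per_second", "IL-1/IL-1R dissociation"),
    "k_off_il1ra": (1e-3, "per_second", "IL-1Ra/IL-1R dissociation"),
    "k_on_osm": (1e-4, "per_molecule_per_second", "OSM binding to OSMR"),
    "k_off_osm": (1e-3, "per_second", "OSM/OSMR dissociation"),
    "k_off_osmra": (7e-05, "per_second", "OSMR-antagonist dissociation"),
    "k_on_socs3": (0.1, "per_molecule_per_second", "SOCS-3 binding OSMR (competitive with OSM)"),
    "k_off_socs3": (3e-07, "per_second", "SOCS-3/OSMR dissociation"),
    "k_int_socs3_osmr": (1e-3, "per_second", "internalization/degradation of SOCS-3-bound OSMR"),
    # IL-1 cascade
    "k_phos_irak2": (1e-5, "per_molecule_per_second", "IRAK-2 phosphorylation by the active IL-1 receptor complex"),
    "k_dephos_irak2": (1e-4, "per_second", "constitutive IRAK-2 dephosphorylation"),
    "k_on_irak2_traf6": (1e-5, "per_molecule_per_second", "pIRAK-2/TRAF6 complex formation"),
    "k_off_irak2_traf6": (1e-4, "per_second", "pIRAK-2/TRAF6 dissociation"),
    "k_phos_jnk": (1e-08, "per_molecule_per_second", "JNK phosphorylation by IRAK-2/TRAF6"),
    "k_dephos_jnk_mkp1": (2e-05, "per_molecule_per_second", "pJNK dephosphorylation by MKP-1"),
    "k_dephos_jnk": (0.0001, "per_second", "constitutive pJNK dephosphorylation"),
    "k_phos_p38": (1e-5, "per_molecule_per_second", "p38 phosphorylation by IRAK-2/TRAF6"),
    "k_dephos_p38_mkp1": (1e-06, "per_molecule_per_second", "p-p38 dephosphorylation by MKP-1"),
    "k_dephos_p38": (1e-5, "per_second", "constitutive p-p38 dephosphorylation"),
    "k_phoscJun": (1e-4, "per_molecule_per_second", "c-Jun phosphorylation by pJNK"),
    "k_dim_cjun": (0.0001, "per_molecule_per_second", "phospho-c-Jun homodimerization"),
    "k_undim_cjun": (1e-3, "per_second", "c-Jun homodimer dissociation"),
    "k_on_pp4_traf6": (0.0002, "per_molecule_per_second", "PP-4 sequestration of TRAF6"),
    "k_off_pp4_traf6": (1e-4, "per_second", "PP-4/TRAF6 dissociation"),
    # OSM cascade
    "k_phos_jak1": (0.001, "per_molecule_per_second", "JAK-1 phosphorylation by the active OSM receptor complex"),
    "k_dephos_jak1": (0.05, "per_second", "constitutive JAK-1 dephosphorylation"),
    "k_phosSTAT3": (5e-3, "per_molecule_per_second", "STAT-3 phosphorylation by pJAK-1"),
    "k_syn_stat3": (5e-3, "per_second", "constitutive STAT-3 synthesis"),
    "k_deg_stat3": (1e-5, "per_second", "free STAT-3 turnover"),
    "k_import_stat3": (0.0002, "per_second", "pSTAT-3 nuclear import"),
    "k_dephos_stat3_ptprt": (2e-05, "per_molecule_per_second", "nuclear pSTAT-3 dephosphorylation by PTPRT"),
    "k_dephos_stat3": (0.00018244, "per_second", "basal nuclear pSTAT-3 dephosphorylation"),
    "k_export_stat3": (2e-05, "per_second", "STAT-3 nuclear export"),
    "k_phoscFos": (5e-7, "per_molecule_per_second", "c-Fos phosphorylation by p-p38"),
    "k_dephos_cfos_dusp16": (1e-6, "per_molecule_per_second", "phospho-c-Fos dephosphorylation by DUSP-16"),
    "k_dephos_cfos_ppase": (2.8e-06, "per_molecule_per_second", "phospho-c-Fos dephosphorylation by the generic phosphatase"),
    "k_on_ap1": (1e-06, "per_molecule_per_second", "AP-1 assembly (pc-Fos + pc-Jun)"),
    "k_off_ap1": (0.003, "per_second", "AP-1 dissociation"),
    "k_on_sp1_gene": (5e-06, "per_molecule_per_second", "Sp-1 binding the TIMP-1 repressive element"),
    "k_off_sp1_gene": (1e-4, "per_second", "Sp-1 leaving the TIMP-1 repressive element"),
    # transcription: weak (c-Jun homodimer) context
    "k_tx_MMP1_lo": (0.001, "per_second", "MMP-1 transcription by the c-Jun homodimer"),
    "k_tx_MMP3_lo": (0.001, "per_second", "MMP-3 transcription by the c-Jun homodimer"),
    "k_tx_MMP13_lo": (0.0001, "per_second", "MMP-13 transcription by the c-Jun homodimer (1/10 of MMP-1)"),
    "k_tx_ADAMTS4_lo": (3.25e-06, "per_second", "ADAMTS-4 transcription by the c-Jun homodimer"),
    "k_tx_cJun_lo": (1e-05, "per_second", "c-Jun transcription by the c-Jun homodimer"),
    "k_syn_PP4_lo": (0.0003, "per_second", "one-step PP-4 synthesis driven by the c-Jun homodimer"),
    "k_syn_DUSP16_lo": (1e-4, "per_second", "one-step DUSP-16 synthesis driven by the c-Jun homodimer"),
    "k_syn_MKP1_lo": (8e-05, "per_second", "one-step MKP-1 synthesis driven by the c-Jun homodimer"),
    # transcription: strong (AP-1) context
    "k_tx_MMP1_hi": (0.065401, "per_second", "MMP-1 transcription by AP-1"),
    "k_tx_MMP3_hi": (0.0165, "per_second", "MMP-3 transcription by AP-1"),
    "k_tx_MMP13_hi": (0.0065401, "per_second", "MMP-13 transcription by AP-1 (1/10 of MMP-1)"),
    "k_tx_ADAMTS4_hi": (0.0118, "per_second", "ADAMTS-4 transcription by AP-1"),
    "k_tx_cJun_hi": (0.001007, "per_second", "c-Jun transcription by AP-1"),
    "k_tx_cFos_hi": (0.0003356, "per_second", "c-Fos transcription by AP-1"),
    "k_tx_TIMP1_hi": (0.00118, "per_molecule_per_second", "TIMP-1 transcription by AP-1 (promoter-gated)"),
    "k_tx_TIMP3_hi": (0.00118, "per_second", "TIMP-3 transcription by AP-1"),
    "k_syn_PP4_hi": (0.003356, "per_second", "one-step PP-4 synthesis driven by AP-1"),
    "k_syn_DUSP16_hi": (8e-05, "per_second", "one-step DUSP-16 synthesis driven by AP-1"),
    "k_syn_MKP1_hi": (0.0001342, "per_second", "one-step MKP-1 synthesis driven by AP-1"),
    "k_syn_Sp1_hi": (0.006711, "per_second", "one-step Sp-1 synthesis driven by AP-1"),
    # transcription: STAT-3 context
    "k_tx_cFos_stat": (0.009, "per_second", "c-Fos transcription by nuclear pSTAT-3"),
    "k_syn_PTPRT_stat": (0.0001, "per_second", "one-step PTPRT synthesis driven by nuclear pSTAT-3"),
    "k_syn_SOCS3_stat": (0.024, "per_second", "one-step SOCS-3 synthesis driven by nuclear pSTAT-3"),
    "k_tx_TIMP1_stat": (5e-4, "per_molecule_per_second", "TIMP-1 transcription by nuclear pSTAT-3 (promoter-gated)"),
    # basal transcription
    "k_tx_cJun_basal": (0.00128, "per_second", "basal c-Jun transcription"),
    "k_tx_TIMP1_basal": (0.00064, "per_second", "basal TIMP-1 transcription (promoter-gated)"),
    "k_tx_TIMP3_basal": (0.00128, "per_second", "basal TIMP-3 transcription"),
    # translation
    "k_transl_cJun": (0.00018, "per_second", "c-Jun translation"),
    "k_transl_cFos": (2e-3, "per_second", "c-Fos translation"),
    "k_transl_MMP1": (2.2e-05, "per_second", "proMMP-1 translation"),
    "k_transl_MMP3": (2.2e-05, "per_second", "proMMP-3 translation"),
    "k_transl_MMP13": (2.2e-05, "per_second", "proMMP-13 translation"),
    "k_transl_ADAMTS4": (1e-4, "per_second", "ADAMTS-4 translation"),
    "k_transl_TIMP1": (2e-4, "per_second", "TIMP-1 translation"),
    "k_transl_TIMP3": (2e-4, "per_second", "TIMP-3 translation"),
    # decay
    "k_deg_mrna": (6.4e-05, "per_second", "shared mRNA decay (~3 h half-life)"),
    "k_deg_mrna_cfos": (5.8e-4, "per_second", "c-Fos mRNA decay (~20 min half-life)"),
    "k_deg_cjun": (1.4978e-05, "per_second", "c-Jun protein decay"),
    "k_deg_cfos": (3.5251e-05, "per_second", "c-Fos protein decay"),
    "k_deg_ap1": (2e-05, "per_second", "AP-1 complex decay"),
    "k_deg_phosphatase": (1e-4, "per_second", "decay of induced phosphatases (PP-4, MKP-1)"),
    "k_deg_ptprt": (1e-5, "per_second", "PTPRT decay (long-lived nuclear phosphatase)"),
    "k_deg_dusp16": (1e-5, "per_second", "DUSP-16 decay (long-lived phosphatase)"),
    "k_deg_socs3": (1e-05, "per_second", "SOCS-3 decay"),
    "k_deg_sp1": (1e-4, "per_second", "Sp-1 decay"),
    "k_deg_prommp": (2e-5, "per_second", "proMMP decay"),
    "k_removal_mmp": (MMP_REMOVAL, "per_second", "removal of active MMP pools (30 h half-life)"),
    "k_deg_adamts4": (1e-5, "per_second", "ADAMTS-4 decay"),
    "k_deg_timp": (2e-5, "per_second", "TIMP-1/TIMP-3 protein decay"),
    "k_deg_mmpact": (1e-06, "per_second", "MMP-activator decay"),
    # ECM
    "k_act_mmp1": (1e-6, "per_molecule_per_second", "proMMP-1 activation by the MMP activator"),
    "k_act_mmp3": (1e-6, "per_molecule_per_second", "proMMP-3 activation by the MMP activator"),
    "k_act3_mmp1": (1e-7, "per_molecule_per_second", "proMMP-1 activation by active MMP-3"),
    "k_act3_mmp13": (1e-7, "per_molecule_per_second", "proMMP-13 activation by active MMP-3"),
    "k_cleave_agg": (2.393334e-09, "per_molecule_per_second", "ADAMTS-4 cleavage of the aggrecan-collagen complex"),
    "k_cleave_coll_mmp1": (2.0083e-11, "per_molecule_per_second", "collagenolysis by MMP-1"),
    "k_cleave_coll_mmp13": (2.0083e-10, "per_molecule_per_second", "collagenolysis by MMP-13 (more active than MMP-1)"),
    "k_on_timp1_mmp": (1e-5, "per_molecule_per_second", "TIMP-1 binding active MMPs (preferred)"),
    "k_on_timp1_adamts": (1e-8, "per_molecule_per_second", "TIMP-1 binding ADAMTS-4 (weak)"),
    "k_on_timp3_adamts": (2e-06, "per_molecule_per_second", "TIMP-3 binding ADAMTS-4 (preferred)"),
    "k_on_timp3_mmp": (1e-7, "per_molecule_per_second", "TIMP-3 binding active MMPs (weak)"),
    "k_off_timp1": (0.001, "per_second", "TIMP-1-enzyme complex dissociation"),
    "k_off_timp3": (1e-6, "per_second", "TIMP-3-enzyme complex dissociation (tighter)"),
    "k_syn_mmpact": (9.2899e-08, "per_second", "one-step MMP-activator synthesis driven by AP-1 (small)"),
    # treatment doses, expressed as initial-amount parameters
    "il1_dose": (1000.0, "per_second", "molecules of IL-1 added in a treatment (initial amount)"),
    "osm_dose": (2000.0, "per_second", "molecules of OSM added in a treatment (initial amount)"),
    "mmpact_dose": (10000.0, "per_second", "molecules of MMP activator added in a treatment (initial amount)"),
}

#: genes transcribed by each transcription-factor context
LOW_TARGET_GENES = ("cJun", "MMP1", "MMP3", "MMP13", "ADAMTS4", "PP4", "DUSP16", "MKP1")
HIGH_TARGET_GENES = (
    "cFos", "cJun", "MMP1", "MMP3", "MMP13", "ADAMTS4",
    "DUSP16", "PP4", "MKP1", "Sp1", "TIMP1", "TIMP3",
)
STAT_TARGET_GENES = ("cFos", "PTPRT", "SOCS3", "TIMP1")
BASAL_GENES = ("cJun", "TIMP1", "TIMP3")

#: initial molecule counts of the untreated cell
INITIAL_AMOUNTS = {
    "IL1R": 100, "OSMR": 100,
    "IRAK2": 200, "TRAF6": 200, "JNK": 200, "p38": 200,
    "JAK1": 200, "STAT3": 500,
    "cJun": 200, "mRNA_cJun": 20,
    "Ppase": 100, "TIMP1_gene": 2,
    "mRNA_TIMP1": 20, "mRNA_TIMP3": 20,
    "TIMP1": 200, "TIMP3": 200,
    "AggColl": 10000,
}


def _params(ids):
    out = []
    for pid in ids:
        value, units, desc = BASELINE_PARAMETERS[pid]
        out.append(RateParameter(pid, value, units, desc))
    return out


def _sp(sid, name, comp, role, init=0):
    return SpeciesDef(sid, name, comp, INITIAL_AMOUNTS.get(sid, init), role)


def _rx(rid, reactants, products, modifiers, k, anchor=""):
    return ReactionDef(rid, dict(reactants), dict(products), tuple(modifiers), k, anchor)


def _decay(sid, k):
    return _rx(f"deg_{sid}", {sid: 1}, {}, (), k, "first-order removal")


# shared species definitions, so that interface species are identical across
# fragments (composition requires exact agreement)
_SHARED_SPECIES = {
    "TRAF6": _sp("TRAF6", "TRAF6", "cytoplasm", "kinase"),
    "pp38": _sp("pp38", "phospho-p38", "cytoplasm", "kinase"),
    "pcJun": _sp("pcJun", "phospho-c-Jun", "nucleus", "transcription_factor"),
    "PP4": _sp("PP4", "protein phosphatase 4", "cytoplasm", "phosphatase"),
    "DUSP16": _sp("DUSP16", "DUSP-16", "cytoplasm", "phosphatase"),
    "MKP1": _sp("MKP1", "MKP-1 (DUSP-1)", "cytoplasm", "phosphatase"),
    "TIMP1_gene": _sp("TIMP1_gene", "free TIMP-1 promoter", "nucleus", "complex"),
    "mRNA_MMP1": _sp("mRNA_MMP1", "MMP-1 mRNA", "cytoplasm", "transcript"),
    "mRNA_MMP3": _sp("mRNA_MMP3", "MMP-3 mRNA", "cytoplasm", "transcript"),
    "mRNA_MMP13": _sp("mRNA_MMP13", "MMP-13 mRNA", "cytoplasm", "transcript"),
    "mRNA_ADAMTS4": _sp("mRNA_ADAMTS4", "ADAMTS-4 mRNA", "cytoplasm", "transcript"),
    "mRNA_TIMP1": _sp("mRNA_TIMP1", "TIMP-1 mRNA", "cytoplasm", "transcript"),
    "mRNA_TIMP3": _sp("mRNA_TIMP3", "TIMP-3 mRNA", "cytoplasm", "transcript"),
    "proMMP1": _sp("proMMP1", "proMMP-1", "matrix", "proenzyme"),
    "proMMP3": _sp("proMMP3", "proMMP-3", "matrix", "proenzyme"),
    "proMMP13": _sp("proMMP13", "proMMP-13", "matrix", "proenzyme"),
    "ADAMTS4": _sp("ADAMTS4", "ADAMTS-4", "matrix", "enzyme"),
    "TIMP1": _sp("TIMP1", "TIMP-1", "matrix", "inhibitor"),
    "TIMP3": _sp("TIMP3", "TIMP-3", "matrix", "inhibitor"),
    "AP1": _sp("AP1", "AP-1 (pc-Fos/pc-Jun)", "nucleus", "transcription_factor"),
    "MMPact": _sp("MMPact", "MMP activator", "matrix", "enzyme"),
}


def build_il1_module() -> ModelFragment:
    """IL-1 arm: receptor engagement through c-Jun-homodimer transcription.

    Includes the weak (homodimer-driven) transcription of the eight target
    genes, basal transcription of c-Jun/TIMP-1/TIMP-3, translation of the
    species with mRNA, one-step synthesis of PP-4, DUSP-16 and MKP-1, and
    first-order decay of every expressed species it owns.
    """
    sh = _SHARED_SPECIES
    species = [
        _sp("IL1", "interleukin-1", "cytoplasm", "ligand"),
        _sp("IL1R", "IL-1 receptor", "cytoplasm", "receptor"),
        _sp("IL1_IL1R", "IL-1/IL-1R complex", "cytoplasm", "complex"),
        _sp("IL1Ra", "IL-1 receptor antagonist", "cytoplasm", "antagonist"),
        _sp("IL1Ra_IL1R", "IL-1Ra/IL-1R complex", "cytoplasm", "complex"),
        _sp("IRAK2", "IRAK-2", "cytoplasm", "kinase"),
        _sp("pIRAK2", "phospho-IRAK-2", "cytoplasm", "kinase"),
        sh["TRAF6"],
        _sp("IRAK2_TRAF6", "IRAK-2/TRAF6 complex", "cytoplasm", "complex"),
        _sp("JNK", "JNK", "cytoplasm", "kinase"),
        _sp("pJNK", "phospho-JNK", "cytoplasm", "kinase"),
        _sp("p38", "p38", "cytoplasm", "kinase"),
        sh["pp38"],
        _sp("cJun", "c-Jun", "nucleus", "transcription_factor"),
        sh["pcJun"],
        _sp("pcJun_dimer", "phospho-c-Jun homodimer", "nucleus", "transcription_factor"),
        _sp("mRNA_cJun", "c-Jun mRNA", "cytoplasm", "transcript"),
        sh["PP4"], sh["DUSP16"], sh["MKP1"], sh["TIMP1_gene"],
        sh["mRNA_MMP1"], sh["mRNA_MMP3"], sh["mRNA_MMP13"], sh["mRNA_ADAMTS4"],
        sh["mRNA_TIMP1"], sh["mRNA_TIMP3"],
        sh["proMMP1"], sh["proMMP3"], sh["proMMP13"], sh["ADAMTS4"],
        sh["TIMP1"], sh["TIMP3"],
    ]
    rx = [
        _rx("bind_il1", {"IL1": 1, "IL1R": 1}, {"IL1_IL1R": 1}, (), "k_on_il1",
            "IL-1 binds its receptor"),
        _rx("unbind_il1", {"IL1_IL1R": 1}, {"IL1": 1, "IL1R": 1}, (), "k_off_il1"),
        _rx("bind_il1ra", {"IL1Ra": 1, "IL1R": 1}, {"IL1Ra_IL1R": 1}, (), "k_on_il1",
            "receptor antagonist competes for IL-1R with the ligand on-rate, no signalling"),
        _rx("unbind_il1ra", {"IL1Ra_IL1R": 1}, {"IL1Ra": 1, "IL1R": 1}, (), "k_off_il1ra"),
        _rx("phos_irak2", {"IRAK2": 1}, {"pIRAK2": 1}, ("IL1_IL1R",), "k_phos_irak2",
            "active receptor complex phosphorylates IRAK-2"),
        _rx("dephos_irak2", {"pIRAK2": 1}, {"IRAK2": 1}, (), "k_dephos_irak2"),
        _rx("bind_irak2_traf6", {"pIRAK2": 1, "TRAF6": 1}, {"IRAK2_TRAF6": 1}, (),
            "k_on_irak2_traf6", "phospho-IRAK-2 recruits TRAF6"),
        _rx("unbind_irak2_traf6", {"IRAK2_TRAF6": 1}, {"pIRAK2": 1, "TRAF6": 1}, (),
            "k_off_irak2_traf6"),
        _rx("phos_jnk", {"JNK": 1}, {"pJNK": 1}, ("IRAK2_TRAF6",), "k_phos_jnk",
            "IRAK-2/TRAF6 phosphorylates JNK"),
        _rx("dephos_jnk_mkp1", {"pJNK": 1}, {"JNK": 1}, ("MKP1",), "k_dephos_jnk_mkp1",
            "induced MKP-1 dephosphorylates pJNK (negative feedback)"),
        _rx("dephos_jnk", {"pJNK": 1}, {"JNK": 1}, (), "k_dephos_jnk"),
        _rx("phos_p38", {"p38": 1}, {"pp38": 1}, ("IRAK2_TRAF6",), "k_phos_p38",
            "IRAK-2/TRAF6 phosphorylates p38"),
        _rx("dephos_p38_mkp1", {"pp38": 1}, {"p38": 1}, ("MKP1",), "k_dephos_p38_mkp1",
            "induced MKP-1 dephosphorylates p-p38 (negative feedback)"),
        _rx("dephos_p38", {"pp38": 1}, {"p38": 1}, (), "k_dephos_p38"),
        _rx("phos_cjun", {"cJun": 1}, {"pcJun": 1}, ("pJNK",), "k_phoscJun",
            "pJNK phosphorylates c-Jun"),
        _rx("dim_cjun", {"pcJun": 2}, {"pcJun_dimer": 1}, (), "k_dim_cjun",
            "phospho-c-Jun homodimerizes (weak transcription factor)"),
        _rx("undim_cjun", {"pcJun_dimer": 1}, {"pcJun": 2}, (), "k_undim_cjun"),
    ]
    # weak transcription by the homodimer: 8 target genes
    for gene in ("cJun", "MMP1", "MMP3", "MMP13", "ADAMTS4"):
        rx.append(_rx(f"tx_{gene}_lo", {}, {f"mRNA_{gene}": 1}, ("pcJun_dimer",),
                      f"k_tx_{gene}_lo", "weak transcription by the c-Jun homodimer"))
    for gene in ("PP4", "DUSP16", "MKP1"):
        rx.append(_rx(f"syn_{gene}_lo", {}, {gene: 1}, ("pcJun_dimer",),
                      f"k_syn_{gene}_lo", "one-step synthesis driven by the c-Jun homodimer"))
    # basal, transcription-factor-independent transcription
    rx += [
        _rx("tx_cJun_basal", {}, {"mRNA_cJun": 1}, (), "k_tx_cJun_basal",
            "basal c-Jun transcription"),
        _rx("tx_TIMP1_basal", {}, {"mRNA_TIMP1": 1}, ("TIMP1_gene",), "k_tx_TIMP1_basal",
            "basal TIMP-1 transcription, gated by the free promoter"),
        _rx("tx_TIMP3_basal", {}, {"mRNA_TIMP3": 1}, (), "k_tx_TIMP3_basal",
            "basal TIMP-3 transcription"),
    ]
    # translation
    for gene, prot in (("cJun", "cJun"), ("MMP1", "proMMP1"), ("MMP3", "proMMP3"),
                       ("MMP13", "proMMP13"), ("ADAMTS4", "ADAMTS4"),
                       ("TIMP1", "TIMP1"), ("TIMP3", "TIMP3")):
        rx.append(_rx(f"transl_{gene}", {}, {prot: 1}, (f"mRNA_{gene}",),
                      f"k_transl_{gene}", "translation"))
    # decay of owned expressed species
    for mid in ("mRNA_cJun", "mRNA_MMP1", "mRNA_MMP3", "mRNA_MMP13",
                "mRNA_ADAMTS4", "mRNA_TIMP1", "mRNA_TIMP3"):
        rx.append(_decay(mid, "k_deg_mrna"))
    rx += [
        _decay("cJun", "k_deg_cjun"),
        _decay("pcJun", "k_deg_cjun"),
        _decay("pcJun_dimer", "k_deg_cjun"),
        _decay("PP4", "k_deg_phosphatase"),
        _decay("DUSP16", "k_deg_dusp16"),
        _decay("MKP1", "k_deg_phosphatase"),
    ]
    pids = sorted({r.rate_constant for r in rx})
    return ModelFragment(
        name="il1_signalling",
        species=species,
        reactions=rx,
        parameters=_params(pids),
        interface_species=[
            "TRAF6", "pp38", "pcJun", "PP4", "DUSP16", "MKP1", "TIMP1_gene",
            "mRNA_MMP1", "mRNA_MMP3", "mRNA_MMP13", "mRNA_ADAMTS4",
            "mRNA_TIMP1", "mRNA_TIMP3",
            "proMMP1", "proMMP3", "proMMP13", "ADAMTS4", "TIMP1", "TIMP3",
        ],
    )


def build_osm_module() -> ModelFragment:
    """OSM arm: OSMR/JAK-1/STAT-3 signalling, c-Fos induction and AP-1.

    The strong (AP-1-driven) transcription of the twelve target genes lives
    here, as do the SOCS-3 and PP-4 negative feedback loops and the Sp-1
    repression of the TIMP-1 promoter.
    """
    sh = _SHARED_SPECIES
    species = [
        _sp("OSM", "oncostatin M", "cytoplasm", "ligand"),
        _sp("OSMR", "OSM receptor", "cytoplasm", "receptor"),
        _sp("OSM_OSMR", "OSM/OSMR complex", "cytoplasm", "complex"),
        _sp("OSMRa", "OSMR antagonist", "cytoplasm", "antagonist"),
        _sp("OSMRa_OSMR", "OSMR-antagonist/OSMR complex", "cytoplasm", "complex"),
        _sp("SOCS3", "SOCS-3", "cytoplasm", "inhibitor"),
        _sp("SOCS3_OSMR", "SOCS-3/OSMR complex", "cytoplasm", "complex"),
        _sp("JAK1", "JAK-1", "cytoplasm", "kinase"),
        _sp("pJAK1", "phospho-JAK-1", "cytoplasm", "kinase"),
        _sp("STAT3", "STAT-3", "cytoplasm", "transcription_factor"),
        _sp("pSTAT3", "phospho-STAT-3", "cytoplasm", "transcription_factor"),
        _sp("pSTAT3_nuc", "nuclear phospho-STAT-3", "nucleus", "transcription_factor"),
        _sp("STAT3_nuc", "nuclear STAT-3", "nucleus", "transcription_factor"),
        _sp("PTPRT", "PTPRT", "nucleus", "phosphatase"),
        _sp("mRNA_cFos", "c-Fos mRNA", "cytoplasm", "transcript"),
        _sp("cFos", "c-Fos", "nucleus", "transcription_factor"),
        _sp("pcFos", "phospho-c-Fos", "nucleus", "transcription_factor"),
        _sp("Ppase", "generic phosphatase", "nucleus", "phosphatase"),
        _sp("Sp1", "Sp-1", "nucleus", "transcription_factor"),
        _sp("Sp1_TIMP1_gene", "Sp-1-bound TIMP-1 promoter", "nucleus", "complex"),
        _sp("PP4_TRAF6", "PP-4/TRAF6 complex", "cytoplasm", "complex"),
        sh["AP1"],
        sh["TRAF6"], sh["pp38"], sh["pcJun"], sh["PP4"], sh["DUSP16"], sh["MKP1"],
        sh["TIMP1_gene"],
        sh["mRNA_MMP1"], sh["mRNA_MMP3"], sh["mRNA_MMP13"], sh["mRNA_ADAMTS4"],
        sh["mRNA_TIMP1"], sh["mRNA_TIMP3"],
    ]
    rx = [
        _rx("bind_osm", {"OSM": 1, "OSMR": 1}, {"OSM_OSMR": 1}, (), "k_on_osm",
            "OSM binds its receptor"),
        _rx("unbind_osm", {"OSM_OSMR": 1}, {"OSM": 1, "OSMR": 1}, (), "k_off_osm"),
        _rx("bind_osmra", {"OSMRa": 1, "OSMR": 1}, {"OSMRa_OSMR": 1}, (), "k_on_osm",
            "OSMR antagonist competes with the ligand on-rate, no signalling"),
        _rx("unbind_osmra", {"OSMRa_OSMR": 1}, {"OSMRa": 1, "OSMR": 1}, (), "k_off_osmra"),
        _rx("bind_socs3", {"SOCS3": 1, "OSMR": 1}, {"SOCS3_OSMR": 1}, (), "k_on_socs3",
            "SOCS-3 binds OSMR in competition with OSM (negative feedback)"),
        _rx("unbind_socs3", {"SOCS3_OSMR": 1}, {"SOCS3": 1, "OSMR": 1}, (), "k_off_socs3"),
        _rx("internalize_socs3_osmr", {"SOCS3_OSMR": 1}, {}, (), "k_int_socs3_osmr",
            "SOCS-3-bound receptor is internalized and degraded (terminates OSM signalling)"),
        _rx("phos_jak1", {"JAK1": 1}, {"pJAK1": 1}, ("OSM_OSMR",), "k_phos_jak1",
            "active OSM receptor complex phosphorylates JAK-1"),
        _rx("dephos_jak1", {"pJAK1": 1}, {"JAK1": 1}, (), "k_dephos_jak1"),
        _rx("phos_stat3", {"STAT3": 1}, {"pSTAT3": 1}, ("pJAK1",), "k_phosSTAT3",
            "pJAK-1 phosphorylates STAT-3"),
        _rx("syn_stat3", {}, {"STAT3": 1}, (), "k_syn_stat3",
            "constitutive STAT-3 synthesis (maintains the basal pool)"),
        _rx("deg_stat3", {"STAT3": 1}, {}, (), "k_deg_stat3",
            "turnover of free cytoplasmic STAT-3"),
        _rx("import_stat3", {"pSTAT3": 1}, {"pSTAT3_nuc": 1}, (), "k_import_stat3",
            "pSTAT-3 nuclear import"),
        _rx("dephos_stat3_ptprt", {"pSTAT3_nuc": 1}, {"STAT3_nuc": 1}, ("PTPRT",),
            "k_dephos_stat3_ptprt", "PTPRT dephosphorylates nuclear pSTAT-3"),
        _rx("dephos_stat3", {"pSTAT3_nuc": 1}, {"STAT3_nuc": 1}, (), "k_dephos_stat3"),
        _rx("export_stat3", {"STAT3_nuc": 1}, {"STAT3": 1}, (), "k_export_stat3",
            "dephosphorylated STAT-3 returns to the cytoplasm"),
        _rx("transl_cFos", {}, {"cFos": 1}, ("mRNA_cFos",), "k_transl_cFos"),
        _rx("phos_cfos", {"cFos": 1}, {"pcFos": 1}, ("pp38",), "k_phoscFos",
            "p-p38 phosphorylates c-Fos"),
        _rx("dephos_cfos_dusp16", {"pcFos": 1}, {"cFos": 1}, ("DUSP16",),
            "k_dephos_cfos_dusp16", "DUSP-16 dephosphorylates phospho-c-Fos"),
        _rx("dephos_cfos_ppase", {"pcFos": 1}, {"cFos": 1}, ("Ppase",),
            "k_dephos_cfos_ppase", "an unspecified phosphatase dephosphorylates phospho-c-Fos"),
        _rx("bind_ap1", {"pcFos": 1, "pcJun": 1}, {"AP1": 1}, (), "k_on_ap1",
            "phospho-c-Fos reversibly binds phospho-c-Jun: the AP-1 complex"),
        _rx("unbind_ap1", {"AP1": 1}, {"pcFos": 1, "pcJun": 1}, (), "k_off_ap1"),
        _rx("bind_sp1_gene", {"Sp1": 1, "TIMP1_gene": 1}, {"Sp1_TIMP1_gene": 1}, (),
            "k_on_sp1_gene", "Sp-1 occludes the TIMP-1 promoter (repression)"),
        _rx("unbind_sp1_gene", {"Sp1_TIMP1_gene": 1}, {"Sp1": 1, "TIMP1_gene": 1}, (),
            "k_off_sp1_gene"),
        _rx("bind_pp4_traf6", {"PP4": 1, "TRAF6": 1}, {"PP4_TRAF6": 1}, (),
            "k_on_pp4_traf6", "PP-4 sequesters TRAF6 away from IRAK-2 (negative feedback)"),
        _rx("unbind_pp4_traf6", {"PP4_TRAF6": 1}, {"PP4": 1, "TRAF6": 1}, (),
            "k_off_pp4_traf6"),
    ]
    # STAT-3 transcription targets
    rx += [
        _rx("tx_cFos_stat", {}, {"mRNA_cFos": 1}, ("pSTAT3_nuc",), "k_tx_cFos_stat",
            "nuclear pSTAT-3 transcribes c-Fos"),
        _rx("syn_PTPRT_stat", {}, {"PTPRT": 1}, ("pSTAT3_nuc",), "k_syn_PTPRT_stat",
            "one-step PTPRT synthesis driven by nuclear pSTAT-3"),
        _rx("syn_SOCS3_stat", {}, {"SOCS3": 1}, ("pSTAT3_nuc",), "k_syn_SOCS3_stat",
            "one-step SOCS-3 synthesis driven by nuclear pSTAT-3"),
        _rx("tx_TIMP1_stat", {}, {"mRNA_TIMP1": 1}, ("pSTAT3_nuc", "TIMP1_gene"),
            "k_tx_TIMP1_stat", "nuclear pSTAT-3 drives TIMP-1 transcription (promoter-gated)"),
    ]
    # strong transcription by AP-1: 12 target genes
    for gene in ("cFos", "cJun", "MMP1", "MMP3", "MMP13", "ADAMTS4", "TIMP3"):
        rx.append(_rx(f"tx_{gene}_hi", {}, {f"mRNA_{gene}": 1}, ("AP1",),
                      f"k_tx_{gene}_hi", "strong transcription by AP-1"))
    rx.append(_rx("tx_TIMP1_hi", {}, {"mRNA_TIMP1": 1}, ("AP1", "TIMP1_gene"),
                  "k_tx_TIMP1_hi", "strong TIMP-1 transcription by AP-1, promoter-gated"))
    for gene in ("PP4", "DUSP16", "MKP1", "Sp1"):
        rx.append(_rx(f"syn_{gene}_hi", {}, {gene: 1}, ("AP1",),
                      f"k_syn_{gene}_hi", "one-step synthesis driven by AP-1"))
    rx += [
        _decay("mRNA_cFos", "k_deg_mrna_cfos"),
        _decay("cFos", "k_deg_cfos"),
        _decay("pcFos", "k_deg_cfos"),
        _decay("AP1", "k_deg_ap1"),
        _decay("SOCS3", "k_deg_socs3"),
        _decay("PTPRT", "k_deg_ptprt"),
        _decay("Sp1", "k_deg_sp1"),
    ]
    pids = sorted({r.rate_constant for r in rx})
    return ModelFragment(
        name="osm_signalling",
        species=species,
        reactions=rx,
        parameters=_params(pids),
        interface_species=[
            "TRAF6", "pp38", "pcJun", "PP4", "DUSP16", "MKP1", "TIMP1_gene", "AP1",
            "mRNA_MMP1", "mRNA_MMP3", "mRNA_MMP13", "mRNA_ADAMTS4",
            "mRNA_TIMP1", "mRNA_TIMP3",
        ],
    )


def build_ecm_module() -> ModelFragment:
    """ECM arm: proMMP activation, TIMP inhibition, matrix degradation.

    Aggrecan is bound to collagen as a complex; ADAMTS-4 cleavage releases
    aggrecan fragments and exposes collagen, which MMP-1/MMP-13 then cleave.
    The (complex + exposed collagen + fragments) pool is conserved by
    construction.
    """
    sh = _SHARED_SPECIES
    species = [
        sh["proMMP1"], sh["proMMP3"], sh["proMMP13"],
        _sp("MMP1", "active MMP-1", "matrix", "enzyme"),
        _sp("MMP3", "active MMP-3", "matrix", "enzyme"),
        _sp("MMP13", "active MMP-13", "matrix", "enzyme"),
        sh["ADAMTS4"], sh["TIMP1"], sh["TIMP3"], sh["MMPact"], sh["AP1"],
        _sp("TIMP1_MMP1", "TIMP-1/MMP-1 complex", "matrix", "complex"),
        _sp("TIMP1_MMP3", "TIMP-1/MMP-3 complex", "matrix", "complex"),
        _sp("TIMP1_MMP13", "TIMP-1/MMP-13 complex", "matrix", "complex"),
        _sp("TIMP1_ADAMTS4", "TIMP-1/ADAMTS-4 complex", "matrix", "complex"),
        _sp("TIMP3_MMP1", "TIMP-3/MMP-1 complex", "matrix", "complex"),
        _sp("TIMP3_MMP3", "TIMP-3/MMP-3 complex", "matrix", "complex"),
        _sp("TIMP3_MMP13", "TIMP-3/MMP-13 complex", "matrix", "complex"),
        _sp("TIMP3_ADAMTS4", "TIMP-3/ADAMTS-4 complex", "matrix", "complex"),
        _sp("AggColl", "aggrecan-collagen complex", "matrix", "matrix_component"),
        _sp("Coll", "exposed collagen", "matrix", "matrix_component"),
        _sp("CollFrag", "collagen fragments", "matrix", "fragment"),
        _sp("AggFrag", "aggrecan fragments", "matrix", "fragment"),
    ]
    rx = [
        _rx("act_mmp1", {"proMMP1": 1}, {"MMP1": 1}, ("MMPact",), "k_act_mmp1",
            "generic activator processes proMMP-1"),
        _rx("act_mmp3", {"proMMP3": 1}, {"MMP3": 1}, ("MMPact",), "k_act_mmp3",
            "generic activator processes proMMP-3"),
        _rx("act_mmp1_by_mmp3", {"proMMP1": 1}, {"MMP1": 1}, ("MMP3",), "k_act3_mmp1",
            "active MMP-3 activates proMMP-1"),
        _rx("act_mmp13_by_mmp3", {"proMMP13": 1}, {"MMP13": 1}, ("MMP3",), "k_act3_mmp13",
            "active MMP-3 activates proMMP-13"),
        _rx("cleave_agg", {"AggColl": 1}, {"Coll": 1, "AggFrag": 1}, ("ADAMTS4",),
            "k_cleave_agg", "ADAMTS-4 cleaves the aggrecan-collagen complex"),
        _rx("cleave_coll_mmp1", {"Coll": 1}, {"CollFrag": 1}, ("MMP1",),
            "k_cleave_coll_mmp1", "MMP-1 cleaves exposed collagen"),
        _rx("cleave_coll_mmp13", {"Coll": 1}, {"CollFrag": 1}, ("MMP13",),
            "k_cleave_coll_mmp13", "MMP-13 cleaves exposed collagen (higher activity)"),
        _rx("prod_MMPact", {}, {"MMPact": 1}, ("AP1",), "k_syn_mmpact",
            "small AP-1-driven one-step synthesis of the MMP activator"),
        _decay("MMPact", "k_deg_mmpact"),
        _decay("proMMP1", "k_deg_prommp"),
        _decay("proMMP3", "k_deg_prommp"),
        _decay("proMMP13", "k_deg_prommp"),
        _decay("MMP1", "k_removal_mmp"),
        _decay("MMP3", "k_removal_mmp"),
        _decay("MMP13", "k_removal_mmp"),
        _decay("ADAMTS4", "k_deg_adamts4"),
        _decay("TIMP1", "k_deg_timp"),
        _decay("TIMP3", "k_deg_timp"),
    ]
    # TIMP inhibition: tight reversible 1:1 binding, selectivity via on-rates
    for timp, enz, kon in (
        ("TIMP1", "MMP1", "k_on_timp1_mmp"),
        ("TIMP1", "MMP3", "k_on_timp1_mmp"),
        ("TIMP1", "MMP13", "k_on_timp1_mmp"),
        ("TIMP1", "ADAMTS4", "k_on_timp1_adamts"),
        ("TIMP3", "MMP1", "k_on_timp3_mmp"),
        ("TIMP3", "MMP3", "k_on_timp3_mmp"),
        ("TIMP3", "MMP13", "k_on_timp3_mmp"),
        ("TIMP3", "ADAMTS4", "k_on_timp3_adamts"),
    ):
        comp = f"{timp}_{enz}"
        rx.append(_rx(f"bind_{comp}", {timp: 1, enz: 1}, {comp: 1}, (), kon,
                      "tight 1:1 TIMP-enzyme inhibition"))
        koff = "k_off_timp1" if timp == "TIMP1" else "k_off_timp3"
        rx.append(_rx(f"unbind_{comp}", {comp: 1}, {timp: 1, enz: 1}, (), koff))
        rx.append(_decay(comp, "k_removal_mmp"))
    pids = sorted({r.rate_constant for r in rx})
    return ModelFragment(
        name="ecm_degradation",
        species=species,
        reactions=rx,
        parameters=_params(pids),
        interface_species=[
            "proMMP1", "proMMP3", "proMMP13", "ADAMTS4", "TIMP1", "TIMP3", "AP1",
        ],
    )


def compose_integrated_model(fragments, params=None, name="cartilage_breakdown") -> ModelSpec:
    """Merge fragments into a single :class:`ModelSpec`.

    Species shared between fragments must be declared as interface species by
    every fragment that uses them, with identical definitions; a shared
    non-interface id or a definition conflict is a :class:`CompositionError`.
    ``params`` optionally overrides parameter values after the merge.
    """
    species = {}
    owners = {}
    for frag in fragments:
        for sp in frag.species:
            if sp.id not in species:
                species[sp.id] = sp
                owners[sp.id] = [frag]
            else:
                owners[sp.id].append(frag)
                shared_ok = all(sp.id in f.interface_species for f in owners[sp.id])
                if not shared_ok:
                    raise CompositionError(
                        f"species '{sp.id}' is shared between fragments but not "
                        f"declared as an interface species everywhere"
                    )
                if sp != species[sp.id]:
                    raise CompositionError(
                        f"unresolved interface species '{sp.id}': conflicting "
                        f"definitions between fragments"
                    )
    reactions = {}
    for frag in fragments:
        for r in frag.reactions:
            if r.id in reactions:
                raise CompositionError(f"duplicate reaction id '{r.id}'")
            reactions[r.id] = r
    parameters = {}
    for frag in fragments:
        for p in frag.parameters:
            if p.id in parameters and parameters[p.id] != p:
                raise CompositionError(f"conflicting definitions of parameter '{p.id}'")
            parameters[p.id] = p
    # every reaction must reference declared species
    for r in reactions.values():
        missing = r.species_ids() - set(species)
        if missing:
            raise CompositionError(
                f"reaction '{r.id}' references undeclared species {sorted(missing)}"
            )

    # treatment doses ride along as (non-kinetic) parameters whenever the
    # corresponding species is present, so calibration can tune them
    for sid, pid in (("IL1", "il1_dose"), ("OSM", "osm_dose"), ("MMPact", "mmpact_dose")):
        if sid in species and pid not in parameters:
            value, units, desc = BASELINE_PARAMETERS[pid]
            parameters[pid] = RateParameter(pid, value, units, desc)

    conserved = {}
    ids = set(species)
    if {"AggColl", "Coll", "CollFrag"} <= ids:
        conserved["collagen"] = ["AggColl", "Coll", "CollFrag"]
    if {"AggColl", "AggFrag"} <= ids:
        conserved["aggrecan"] = ["AggColl", "AggFrag"]

    model = ModelSpec(
        name=name,
        version="1.0",
        compartments=COMPARTMENTS,
        species=list(species.values()),
        reactions=list(reactions.values()),
        parameters=list(parameters.values()),
        conserved_pools=conserved,
    )
    if params:
        model = model.with_parameters(params)
    # the MMP-1:MMP-13 transcription ratio is a structural constant of the
    # model: 10x in every transcription-factor context, equal mRNA decay
    pm = model.parameter_map()
    for ctx in ("lo", "hi"):
        k1, k13 = f"k_tx_MMP1_{ctx}", f"k_tx_MMP13_{ctx}"
        if k1 in pm and k13 in pm and pm[k13].value > 0:
            ratio = pm[k1].value / pm[k13].value
            if abs(ratio - 10.0) > 1e-6 * ratio:
                raise CompositionError(
                    f"MMP-1:MMP-13 transcription ratio must be 10 ({ctx} context, got {ratio})"
                )
    return model


def build_integrated_model(params=None) -> ModelSpec:
    """The full three-fragment model with baseline parameters."""
    return compose_integrated_model(
        [build_il1_module(), build_osm_module(), build_ecm_module()], params=params
    )


def target_genes(fragment_or_model, tf: str):
    """Genes transcribed (or synthesized one-step) under a transcription factor.

    Scans reactions whose id follows the ``tx_<gene>_<ctx>`` /
    ``syn_<gene>_<ctx>`` convention and whose modifiers include ``tf``.
    """
    genes = set()
    for r in fragment_or_model.reactions:
        if tf in r.modifiers and (r.id.startswith("tx_") or r.id.startswith("syn_")):
            stem = r.id.split("_", 1)[1]
            gene = stem.rsplit("_", 1)[0]
            genes.add(gene)
    return genes


def basal_transcription_genes(fragment_or_model):
    """Genes with transcription-factor-independent (basal) transcription."""
    return {
        r.id[len("tx_"):-len("_basal")]
        for r in fragment_or_model.reactions
        if r.id.startswith("tx_") and r.id.endswith("_basal")
    }


def validate_model(model: ModelSpec):
    """Structural diagnostics: returns a list of problem strings (empty = ok).

    Checks id collisions, orphan species, rate-constant unit/order
    consistency, missing parameter/species references, and conservation of
    the declared matrix pools against the stoichiometry matrix.
    """
    import numpy as np

    problems = []
    seen = set()
    for s in model.species:
        if s.id in seen:
            problems.append(f"duplicate species id '{s.id}'")
        seen.add(s.id)
    seen_r = set()
    for r in model.reactions:
        if r.id in seen_r:
            problems.append(f"duplicate reaction id '{r.id}'")
        seen_r.add(r.id)
    seen_p = {}
    for p in model.parameters:
        if p.id in seen_p:
            problems.append(f"duplicate parameter id '{p.id}'")
        seen_p[p.id] = p

    used = set()
    for r in model.reactions:
        used |= r.species_ids()
        missing = r.species_ids() - {s.id for s in model.species}
        if missing:
            problems.append(f"reaction '{r.id}' references undeclared species {sorted(missing)}")
        if r.rate_constant not in seen_p:
            problems.append(f"reaction '{r.id}' references unknown parameter '{r.rate_constant}'")
        else:
            expected = "per_second" if r.order <= 1 else "per_molecule_per_second"
            # dose parameters are initial amounts, never rate constants
            if seen_p[r.rate_constant].units != expected:
                problems.append(
                    f"reaction '{r.id}' (order {r.order}) uses parameter "
                    f"'{r.rate_constant}' with units {seen_p[r.rate_constant].units}, "
                    f"expected {expected}"
                )
    for s in model.species:
        if s.id not in used:
            problems.append(f"orphan species '{s.id}' appears in no reaction")

    if model.reactions and model.conserved_pools:
        S = model.stoichiometry_matrix()
        idx = model.species_index()
        for pool, members in model.conserved_pools.items():
            v = np.zeros(len(model.species))
            for m in members:
                v[idx[m]] = 1.0
            net = v @ S
            bad = np.nonzero(np.abs(net) > 1e-12)[0]
            for j in bad:
                problems.append(
                    f"reaction '{model.reactions[j].id}' violates conservation of the "
                    f"{pool} pool"
                )
    return problems
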