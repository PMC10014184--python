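"""Synthetic study generator: toy metabolic network and three-group proteome.

The generator emulates the study design of a three-arm mouse experiment
(wild-type + vehicle, disease model + vehicle, disease model + treatment;
n = 3/9/6) with a planted ground truth:

* a toy metabolic network with extracellular (e), cytosolic (c) and
  mitochondrial (m) compartments.  Its fatty-acid branch — uptake,
  cytosolic acyl-CoA activation, carnitine shuttle, iterative
  mitochondrial beta-oxidation to acetyl units — mirrors the carnitine
  shuttle / beta-oxidation pathway, including the OR (isozyme) rules on
  activation/shuttle steps and AND (complex subunit) rules on
  beta-oxidation steps.  A glucose branch keeps biomass feasible when the
  fatty-acid branch is absent.  All internal reactions are elementally
  and charge balanced by construction.
* a protein x sample abundance matrix, log-normal around group means,
  with four planted protein clusters: cluster 1 (up in disease, restored
  by treatment — contains every fatty-acid-branch gene), cluster 4
  (down in disease, restored), clusters 2/3 (disease-insensitive but
  treatment-shifted), plus an unaffected background.

The planted "restored" metabolites are the cytosolic and mitochondrial
acyl-carnitines: their turnover is high only when the fatty-acid branch
is expressed, so a correct pipeline flags them as elevated in disease
and normalised under treatment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import MetabolicNetwork, Metabolite, NetworkError, Reaction, parse_formula

__all__ = [
    "GROUPS",
    "ToyNetworkConfig",
    "EffectSizes",
    "ProteomeMatrix",
    "SyntheticTruth",
    "generate_toy_network",
    "default_medium",
    "fatty_acid_branch_reactions",
    "simulate_proteome",
    "write_fixtures",
    "read_fixtures",
]

GROUPS = ("WT_VEH", "AD_VEH", "AD_NFP")


@dataclass(frozen=True)
class ToyNetworkConfig:
    """Size and bound settings of the toy network.

    ``beta_oxidation_rounds`` sets the cascade length; with the default 3
    rounds the imported fatty acid is a C8 chain degraded to 4 acetyl
    units.  Bounds are in arbitrary flux units (mmol/gDW/h).
    """

    beta_oxidation_rounds: int = 3
    uptake_bound: float = 10.0
    internal_bound: float = 1000.0

    def __post_init__(self) -> None:
        if self.beta_oxidation_rounds < 1:
            raise ValueError("beta_oxidation_rounds must be >= 1")
        if self.uptake_bound <= 0 or self.internal_bound <= 0:
            raise ValueError("bounds must be positive")


@dataclass(frozen=True)
class EffectSizes:
    """Planted log2 effect sizes per cluster and the noise level.

    ``cluster1`` is the disease-elevation of the fatty-acid-branch genes
    (restored under treatment); ``cluster4`` the mirrored depression;
    ``cluster2``/``cluster3`` are treatment-only shifts (up/down).
    ``fa_baseline_offset`` places the branch genes below the expression
    median in unaffected groups so that evidence-based model extraction
    excludes the branch there.  ``cv`` is the log-normal coefficient of
    variation of replicate noise.
    """

    cluster1: float = 3.0
    cluster2: float = 1.5
    cluster3: float = 1.5
    cluster4: float = 3.0
    fa_baseline_offset: float = -2.0
    cv: float = 0.2

    @classmethod
    def null(cls) -> "EffectSizes":
        return cls(cluster1=0.0, cluster2=0.0, cluster3=0.0, cluster4=0.0)


@dataclass
class ProteomeMatrix:
    """Protein x sample abundance matrix with the sample -> group design."""

    abundances: pd.DataFrame
    design: pd.Series  # sample id -> group name

    def __post_init__(self) -> None:
        if list(self.abundances.columns) != list(self.design.index):
            raise ValueError("design index must equal the sample columns")
        if self.abundances.isna().any().any():
            raise ValueError("missing abundances are not allowed")
        if (self.abundances.values <= 0).any():
            raise ValueError("abundances must be positive")
        counts = self.design.value_counts()
        if (counts < 2).any():
            raise ValueError("every group needs >= 2 samples")

    @property
    def proteins(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundances.columns)

    def group_samples(self, group: str) -> list[str]:
        return list(self.design.index[self.design == group])

    def sample_expression(self, sample: str) -> dict[str, float]:
        return self.abundances[sample].to_dict()


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulated study."""

    cluster_of_protein: dict[str, int | None]
    active_reactions_by_group: dict[str, set[str]]
    restored_metabolites: set[str]

    @property
    def fatty_acid_branch(self) -> set[str]:
        return (self.active_reactions_by_group["AD_VEH"]
                - self.active_reactions_by_group["WT_VEH"])


# --------------------------------------------------------------------------
# toy network
# --------------------------------------------------------------------------

def _acyl_formula(n: int) -> str:
    # acyl-CoA of chain length n: fatty acid CnH2nO2 + CoA - H2O
    return f"C{21 + n}H{34 + 2 * n}N7O17P3S"


def _check_balanced(mets: dict[str, Metabolite], rxn: Reaction) -> None:
    residual: dict[str, float] = {}
    charge = 0.0
    for met_id, coef in rxn.stoichiometry.items():
        for elem, cnt in parse_formula(mets[met_id].formula).items():
            residual[elem] = residual.get(elem, 0.0) + coef * cnt
        charge += coef * mets[met_id].charge
    bad = {e: v for e, v in residual.items() if abs(v) > 1e-9}
    if bad or abs(charge) > 1e-9:
        raise NetworkError(f"reaction {rxn.id} is unbalanced: {bad}, charge {charge}")


def generate_toy_network(config: ToyNetworkConfig = ToyNetworkConfig()) -> MetabolicNetwork:
    """Build the carnitine-shuttle / beta-oxidation toy network.

    Deterministic for a fixed config.  Every internal reaction is mass
    and charge balanced; biomass and exchanges are pseudo-reactions.
    """
    R = config.beta_oxidation_rounds
    n_fa = 2 * (R + 1)  # imported fatty-acid chain length
    ub = config.internal_bound
    up = config.uptake_bound

    mets: dict[str, Metabolite] = {}

    def met(mid: str, comp: str, formula: str) -> str:
        if mid not in mets:
            mets[mid] = Metabolite(mid, comp, formula, 0)
        return mid

    for comp in ("e", "c"):
        met(f"glc_{comp}", comp, "C6H12O6")
        met(f"fa_{comp}", comp, f"C{n_fa}H{2 * n_fa}O2")
        met(f"pi_{comp}", comp, "H3O4P")
        met(f"nh4_{comp}", comp, "H3N")
    for comp in ("e", "c", "m"):
        met(f"o2_{comp}", comp, "O2")
        met(f"h2o_{comp}", comp, "H2O")
        met(f"co2_{comp}", comp, "CO2")
    met("pyr_c", "c", "C3H4O3")
    met("pyr_m", "m", "C3H4O3")
    for comp in ("c", "m"):
        met(f"nadox_{comp}", comp, "C21H27N7O14P2")
        met(f"nadred_{comp}", comp, "C21H29N7O14P2")
        met(f"coa_{comp}", comp, "C21H36N7O16P3S")
        met(f"carn_{comp}", comp, "C7H15NO3")
    met("fadox_m", "m", "C27H33N9O15P2")
    met("fadred_m", "m", "C27H35N9O15P2")
    met("accoa_m", "m", _acyl_formula(2))
    met(f"c{n_fa}coa_c", "c", _acyl_formula(n_fa))
    met(f"c{n_fa}carn_c", "c", f"C{7 + n_fa}H{13 + 2 * n_fa}NO4")
    met(f"c{n_fa}carn_m", "m", f"C{7 + n_fa}H{13 + 2 * n_fa}NO4")
    chains = [2 * (R + 1) - 2 * k for k in range(R)]  # e.g. [8, 6, 4]
    for n in chains:
        met(f"c{n}coa_m", "m", _acyl_formula(n))
        met(f"c{n}enoylcoa_m", "m", f"C{21 + n}H{32 + 2 * n}N7O17P3S")
        met(f"c{n}hydroxycoa_m", "m", f"C{21 + n}H{34 + 2 * n}N7O18P3S")
        met(f"c{n}ketocoa_m", "m", f"C{21 + n}H{32 + 2 * n}N7O18P3S")

    rxns: list[Reaction] = []

    def rxn(rid: str, stoich: dict[str, float], lb: float, ub_: float,
            gpr: str = "", balanced: bool = True) -> None:
        merged: dict[str, float] = {}
        for k, v in stoich.items():
            merged[k] = merged.get(k, 0.0) + v
        r = Reaction(rid, {k: v for k, v in merged.items() if v != 0.0}, lb, ub_, gpr)
        if balanced:
            _check_balanced(mets, r)
        rxns.append(r)

    # exchanges (secretion positive, uptake negative; opened by the medium)
    for mid, lo in [("glc_e", -up), ("fa_e", -up), ("o2_e", -2 * up),
                    ("h2o_e", -up), ("pi_e", -up), ("nh4_e", -up), ("co2_e", 0.0)]:
        rxn(f"EX_{mid}", {mid: -1.0}, lo, ub, balanced=False)

    # transports
    rxn("GLCt", {"glc_e": -1, "glc_c": 1}, 0, ub, "Hkg01")
    rxn("FAt", {"fa_e": -1, "fa_c": 1}, 0, ub, "Fatp1")
    rxn("O2t", {"o2_e": -1, "o2_c": 1}, -ub, ub, "Hkg02")
    rxn("O2tm", {"o2_c": -1, "o2_m": 1}, -ub, ub, "Hkg03")
    rxn("H2Ot", {"h2o_e": -1, "h2o_c": 1}, -ub, ub)
    rxn("H2Otm", {"h2o_c": -1, "h2o_m": 1}, -ub, ub)
    rxn("CO2t", {"co2_c": -1, "co2_e": 1}, -ub, ub, "Hkg04")
    rxn("CO2tm", {"co2_m": -1, "co2_c": 1}, -ub, ub, "Hkg05")
    rxn("PIt", {"pi_e": -1, "pi_c": 1}, 0, ub, "Hkg06")
    rxn("NH4t", {"nh4_e": -1, "nh4_c": 1}, 0, ub, "Hkg07")
    rxn("PYRtm", {"pyr_c": -1, "pyr_m": 1}, 0, ub, "Hkg08")

    # glucose branch: lumped glycolysis and pyruvate dehydrogenase
    rxn("GLYC", {"glc_c": -1, "nadox_c": -2, "pyr_c": 2, "nadred_c": 2},
        0, ub, "Hkg09 or Hkg10")
    rxn("PDH", {"pyr_m": -1, "coa_m": -1, "nadox_m": -1,
                "accoa_m": 1, "co2_m": 1, "nadred_m": 1},
        0, ub, "Hkg11 and Hkg12")

    # lumped respiration regenerating the redox carriers
    rxn("RESPNc", {"nadred_c": -1, "o2_c": -0.5, "nadox_c": 1, "h2o_c": 1},
        0, ub, "Hkg13")
    rxn("RESPNm", {"nadred_m": -1, "o2_m": -0.5, "nadox_m": 1, "h2o_m": 1},
        0, ub, "Hkg14")
    rxn("RESPFm", {"fadred_m": -1, "o2_m": -0.5, "fadox_m": 1, "h2o_m": 1},
        0, ub, "Hkg15")

    # fatty-acid branch: activation (OR of isozymes), carnitine shuttle,
    # beta-oxidation rounds (AND of complex subunits)
    rxn("FACOAL", {"fa_c": -1, "coa_c": -1, f"c{n_fa}coa_c": 1, "h2o_c": 1},
        0, ub, "Facl1 or Facl2 or Facl3")
    rxn("CPT1", {f"c{n_fa}coa_c": -1, "carn_c": -1, f"c{n_fa}carn_c": 1, "coa_c": 1},
        0, ub, "Cpts1 or Cpts2")
    rxn("CACT", {f"c{n_fa}carn_c": -1, "carn_m": -1, f"c{n_fa}carn_m": 1, "carn_c": 1},
        -ub, ub, "Cact1")
    rxn("CPT2", {f"c{n_fa}carn_m": -1, "coa_m": -1, f"c{n_fa}coa_m": 1, "carn_m": 1},
        0, ub, "Cptm1 or Cptm2")
    for r_idx, n in enumerate(chains, start=1):
        prod = "accoa_m" if n - 2 == 2 else f"c{n - 2}coa_m"
        rxn(f"ACDH{r_idx}", {f"c{n}coa_m": -1, "fadox_m": -1,
                             f"c{n}enoylcoa_m": 1, "fadred_m": 1},
            0, ub, f"Acdh{r_idx}a and Acdh{r_idx}b")
        rxn(f"ECH{r_idx}", {f"c{n}enoylcoa_m": -1, "h2o_m": -1,
                            f"c{n}hydroxycoa_m": 1},
            0, ub, f"Ech{r_idx}a and Tfpa")
        rxn(f"HACD{r_idx}", {f"c{n}hydroxycoa_m": -1, "nadox_m": -1,
                             f"c{n}ketocoa_m": 1, "nadred_m": 1},
            0, ub, f"Hacd{r_idx}a and Tfpa")
        kt_stoich = {f"c{n}ketocoa_m": -1.0, "coa_m": -1.0, "accoa_m": 1.0}
        kt_stoich[prod] = kt_stoich.get(prod, 0.0) + 1.0  # last round yields 2 acetyl-CoA
        rxn(f"KT{r_idx}", kt_stoich, 0, ub, f"Kt{r_idx}a and Tfpb and Tfpa")

    # biomass drain: acetyl units plus N and P demand (pseudo-reaction)
    rxn("BIOMASS", {"accoa_m": -1, "nh4_c": -0.2, "pi_c": -0.1, "coa_m": 1},
        0, ub, balanced=False)

    return MetabolicNetwork(
        metabolites=list(mets.values()),
        reactions=rxns,
        biomass_id="BIOMASS",
        exchange_ids={r.id for r in rxns if r.id.startswith("EX_")},
    )


def default_medium(config: ToyNetworkConfig = ToyNetworkConfig()) -> dict[str, float]:
    """Uptake limits of the default growth medium (full medium)."""
    up = config.uptake_bound
    return {"EX_glc_e": up, "EX_fa_e": up, "EX_o2_e": 2 * up,
            "EX_pi_e": up, "EX_nh4_e": up, "EX_h2o_e": up}


def fatty_acid_branch_reactions(network: MetabolicNetwork) -> set[str]:
    """Reaction ids of the planted fatty-acid branch (incl. its uptake
    transport and the FAD-linked respiration it alone drives)."""
    branch = {"FAt", "FACOAL", "CPT1", "CACT", "CPT2", "RESPFm"}
    branch |= {r.id for r in network.reactions
               if r.id[:-1] in ("ACDH", "ECH", "HACD", "KT")
               or r.id[:-2] in ("ACDH", "ECH", "HACD", "KT")}
    return branch & set(network.reaction_ids)


# --------------------------------------------------------------------------
# proteome simulator
# --------------------------------------------------------------------------

_BASE_LOG2 = 20.0        # typical log2 intensity of an unaffected protein
_BASE_SD_LOG2 = 1.0      # protein-to-protein baseline spread
_FA_BASE_SD_LOG2 = 0.3   # tighter spread for branch genes (planted design)
_N_BACKGROUND = 60
_N_PLANTED = 12          # planted proteins per non-branch cluster


def simulate_proteome(network: MetabolicNetwork,
                      design: tuple[int, int, int] = (3, 9, 6),
                      effects: EffectSizes = EffectSizes(),
                      seed: int = 0) -> tuple[ProteomeMatrix, SyntheticTruth]:
    """Simulate the three-group proteome with planted cluster structure.

    ``design`` gives the group sizes (control, disease, treated).  The
    abundance of protein p in sample s is log-normal around the group
    mean of p, with coefficient of variation ``effects.cv``.  Setting an
    effect size to zero removes that cluster from the planted truth.
    """
    if any(n < 2 for n in design):
        raise ValueError("every group needs >= 2 samples")
    rng = np.random.default_rng(seed)

    fa_branch = fatty_acid_branch_reactions(network)
    fa_genes = sorted({g for rid in fa_branch for g in network.reaction(rid).genes})
    housekeeping = sorted(network.genes - set(fa_genes))
    planted2 = [f"P2_{i:02d}" for i in range(_N_PLANTED)]
    planted3 = [f"P3_{i:02d}" for i in range(_N_PLANTED)]
    planted4 = [f"P4_{i:02d}" for i in range(_N_PLANTED)]
    background = [f"BG_{i:02d}" for i in range(_N_BACKGROUND)]
    proteins = fa_genes + housekeeping + planted2 + planted3 + planted4 + background

    samples, groups = [], []
    for group, n in zip(GROUPS, design):
        for i in range(1, n + 1):
            samples.append(f"{group}_{i}")
            groups.append(group)
    design_series = pd.Series(groups, index=samples, name="group")

    # per-protein baseline and per-group offsets in log2 space
    base = {}
    offset = {p: dict.fromkeys(GROUPS, 0.0) for p in proteins}
    cluster: dict[str, int | None] = dict.fromkeys(proteins, None)
    for p in fa_genes:
        base[p] = _BASE_LOG2 + effects.fa_baseline_offset + rng.normal(0, _FA_BASE_SD_LOG2)
        if effects.cluster1 != 0.0:
            offset[p]["AD_VEH"] = effects.cluster1
            cluster[p] = 1
    for p in housekeeping + background:
        base[p] = _BASE_LOG2 + rng.normal(0, _BASE_SD_LOG2)
    for p in planted2:
        base[p] = _BASE_LOG2 + rng.normal(0, _BASE_SD_LOG2)
        if effects.cluster2 != 0.0:
            offset[p]["AD_NFP"] = effects.cluster2
            cluster[p] = 2
    for p in planted3:
        base[p] = _BASE_LOG2 + rng.normal(0, _BASE_SD_LOG2)
        if effects.cluster3 != 0.0:
            offset[p]["AD_NFP"] = -effects.cluster3
            cluster[p] = 3
    for p in planted4:
        base[p] = _BASE_LOG2 + rng.normal(0, _BASE_SD_LOG2)
        if effects.cluster4 != 0.0:
            offset[p]["AD_VEH"] = -effects.cluster4
            cluster[p] = 4

    sigma_ln = float(np.sqrt(np.log1p(effects.cv ** 2)))
    data = np.empty((len(proteins), len(samples)))
    for i, p in enumerate(proteins):
        for j, s in enumerate(samples):
            mu = base[p] + offset[p][design_series[s]]
            data[i, j] = 2.0 ** mu * np.exp(rng.normal(0.0, sigma_ln))
    matrix = ProteomeMatrix(
        pd.DataFrame(data, index=proteins, columns=samples), design_series)

    core = set(network.reaction_ids) - fa_branch
    acylcarn = [m.id for m in network.metabolites
                if "carn_" in m.id and not m.id.startswith("carn_")]
    truth = SyntheticTruth(
        cluster_of_protein=cluster,
        active_reactions_by_group={
            "WT_VEH": set(core),
            "AD_VEH": set(core) | (fa_branch if effects.cluster1 != 0.0 else set()),
            "AD_NFP": set(core),
        },
        restored_metabolites=set(acylcarn) if effects.cluster1 != 0.0 else set(),
    )
    return matrix, truth


# --------------------------------------------------------------------------
# fixture I/O
# --------------------------------------------------------------------------

def write_fixtures(network: MetabolicNetwork, proteome: ProteomeMatrix,
                   truth: SyntheticTruth, directory: str | Path) -> dict[str, Path]:
    """Serialize a study to SBML + TSV + JSON; returns the file map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    network.validate()
    paths = {
        "network": directory / "network.xml",
        "proteome": directory / "proteome.tsv",
        "design": directory / "design.tsv",
        "truth": directory / "truth.json",
    }
    network.write_sbml(str(paths["network"]))
    # %.17g keeps doubles bitwise round-trippable through the TSV
    proteome.abundances.to_csv(paths["proteome"], sep="\t", index_label="protein",
                               float_format="%.17g")
    proteome.design.rename("group").to_csv(paths["design"], sep="\t", index_label="sample")
    with open(paths["truth"], "w") as fh:
        json.dump({
            "cluster_of_protein": truth.cluster_of_protein,
            "active_reactions_by_group": {g: sorted(v) for g, v in
                                          truth.active_reactions_by_group.items()},
            "restored_metabolites": sorted(truth.restored_metabolites),
        }, fh, indent=1)
    return paths


def read_fixtures(directory: str | Path) -> tuple[MetabolicNetwork, ProteomeMatrix, SyntheticTruth]:
    directory = Path(directory)
    network = MetabolicNetwork.read_sbml(str(directory / "network.xml"), "BIOMASS")
    abund = pd.read_csv(directory / "proteome.tsv", sep="\t", index_col="protein",
                        float_precision="round_trip")
    design = pd.read_csv(directory / "design.tsv", sep="\t", index_col="sample")["group"]
    proteome = ProteomeMatrix(abund, design)
    with open(directory / "truth.json") as fh:
        raw = json.load(fh)
    truth = SyntheticTruth(
        cluster_of_protein={k: v for k, v in raw["cluster_of_protein"].items()},
        active_reactions_by_group={g: set(v) for g, v in
                                   raw["active_reactions_by_group"].items()},
        restored_metabolites=set(raw["restored_metabolites"]),
    )
    return network, proteome, truth
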