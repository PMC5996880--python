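"""Synthetic LOAEL databases with controlled structure and noise.

Generates two toy databases that mimic the statistical shape of real
chronic-toxicity collections: clusters of structurally related compounds
(a shared scaffold decorated with small substituents, so within-cluster
MolPrint2D Tanimoto similarity is high), a structure–activity signal at the
cluster level, replicate measurements with lognormal noise (Gaussian on the
-log10 scale, SD ``noise_sd_log``), a fraction of compounds present in both
databases (the synthetic "test set"), per-cluster "satellite" analogs whose
similarity to the cluster sits in the intermediate [0.2, 0.5) band (so they
are predictable only with an applicability-domain warning), and a few
structurally isolated singletons that no model should be able to predict.

Everything is deterministic under a fixed seed, including the emitted CSV
files.  Structural constraints are verified at generation time: every
cluster's minimum within-cluster similarity must reach the model's upper
similarity threshold, and every singleton's maximum similarity to any other
compound must stay below the lower threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import canonicalize, tanimoto
from .data import ToxDataset, dataset_from_records

# Scaffold SMILES with one substitution slot.  Chosen to be mutually
# dissimilar ring/chain systems large enough that swapping the terminal
# substituent keeps within-cluster similarity above 0.5.
SCAFFOLDS = [
    "NC(=O)c1ccc(OCC(=O)O)cc1CCC{}",
    "CC(C)Cc1ccc(O)c(N)c1SCCC{}",
    "COc1ccc2[nH]c(C(=O)O)cc2c1CCC{}",
    "OCC1OC(O)C(O)C(O)C1NCCC{}",
    "CC1=CC(=O)CC(C)(C)C1NC(=O)CC{}",
    "Clc1ccc(S(=O)(=O)N2CCOCC2)cc1CC{}",
    "N#Cc1ccc(C(F)(F)F)cc1OCCC{}",
    "O=C(O)C1CCN(C(=O)c2ccco2)CC1CC{}",
    "CN1CCN(c2ncccn2)CC1C(=O)OCC{}",
    "OC(=O)c1cc(Br)sc1NC(=O)CCC{}",
    "CC(=O)Nc1ccc(S(N)(=O)=O)cc1OCC{}",
    "O=C1NC(=O)C(c2ccccc2)(C(=O)N1)CCC{}",
    "COC(=O)C1CC2CCC1(C)C2(C)OCC{}",
    "CC(NC(=O)C1CCCO1)c1cccc(Cl)c1CC{}",
    "CCN(CC)C(=O)c1cccnc1SCCC{}",
    "OC1CCC2(C)C(CCC2=O)C1NC(=O)CC{}",
    "Fc1ccc(C(=O)N2CCC(O)CC2)cc1NCC{}",
    "CSc1nnc(C(C)(C)C)c(=O)n1NCC{}",
    "O=S(=O)(Nc1onc(C)c1Cl)c1ccsc1CC{}",
    "COc1cc(C=O)ccc1OCC(=O)NCC{}",
]

# Small substituents appended at the slot.
SUBSTITUENTS = ["C", "CC", "O", "N", "F", "Cl", "Br", "C(C)C", "OC", "CO", "C#N", "CCl"]

# Bulky substituents for "satellite" analogs: appended at the same slot they
# push the similarity to the small-substituent cluster members into the
# intermediate band [0.2, 0.5), i.e. outside the strict applicability domain
# but still reachable at the lowered threshold.
SATELLITE_SUBSTITUENTS = [
    "c1csc(NC(=O)COc2ccncc2)c1",
    "CN(CCO)CCNC(=S)Nc1ccc(I)cc1",
    "c1ccc(OCC(=O)Nc2ccco2)cc1",
    "OCC1CCN(c2ncncc2F)C1",
    "CC(=O)Oc1ccccc1C(=O)NCCS",
    "Nc1nnc(SCC(=O)NCCO)s1",
    "OC(Cn1ccnc1)c1ccc(F)cc1",
    "COC(=O)C1CCN(S(C)(=O)=O)C1N",
    "CCOP(=O)(OCC)SCCN",
    "CNC(=O)Cc1ccc(Br)nc1",
    "CC1(C)SC2C(NC(=O)CO)C(=O)N2C1",
    "OCC(NC(=S)NCc1ccco1)c1ccccn1",
    "CCOC(=O)c1sc(NC(=O)Cc2ccc(OC)cc2)cc1",
    "CN1C(=O)N(C)c2ncn(CC(O)CSc3nccs3)c2C1=O",
]

# Candidate singletons: small molecules far from every scaffold family.
SINGLETON_POOL = [
    "S=C=S",
    "ClC(Cl)(Cl)Cl",
    "FC(F)(F)F",
    "OP(=O)(O)O",
    "OS(=O)(=O)O",
    "NC(=N)N",
    "O=C(O)C(=O)O",
    "NN",
    "OO",
    "BrCBr",
    "C1CS1",
    "O=C1NC(=O)NC(=O)N1",
    "[O-][N+](=O)O",
    "N#CSC#N",
]


class GenerationError(RuntimeError):
    """A structural constraint could not be satisfied."""


@dataclass
class SyntheticSpec:
    """Conditions of a synthetic two-database study.

    Defaults mirror the statistical structure the package is meant to face:
    replicate noise SD 0.3 on the -log10 scale (the magnitude of observed
    inter-study variability of chronic LOAELs), activities spanning four
    log units, mostly 1–2 replicates per compound per database with an
    occasional 3–4, and about a quarter of the compounds present in both
    databases.
    """

    n_clusters: int = 12
    cluster_size: int = 6
    n_singletons: int = 8
    n_satellites: int = 2
    noise_sd_log: float = 0.3
    activity_range: tuple[float, float] = (0.0, 4.0)
    seed: int = 0
    # replicate counts per database: min(geometric(p), max), at least min
    replicate_geometric_p: float = 0.6
    max_replicates: int = 4
    min_replicates: int = 1
    both_db_fraction: float = 0.25
    substituent_effect_sd: float = 0.15
    satellite_effect_sd: float = 0.35
    # structural-constraint thresholds, matching the engine's tiers
    cluster_similarity_floor: float = 0.5
    singleton_similarity_ceiling: float = 0.2
    max_retries: int = 10

    def validate(self) -> None:
        if min(self.n_clusters, self.cluster_size, self.n_singletons) < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd_log < 0:
            raise ValueError("noise_sd_log must be non-negative")
        if self.n_clusters > len(SCAFFOLDS):
            raise ValueError(f"at most {len(SCAFFOLDS)} clusters supported")
        if self.cluster_size > len(SUBSTITUENTS):
            raise ValueError(f"at most {len(SUBSTITUENTS)} compounds per cluster")
        if self.n_satellites > len(SATELLITE_SUBSTITUENTS):
            raise ValueError(f"at most {len(SATELLITE_SUBSTITUENTS)} satellites per cluster")
        if not 0 <= self.both_db_fraction <= 1:
            raise ValueError("both_db_fraction must be a fraction")


@dataclass
class SyntheticCompound:
    smiles: str
    canonical_smiles: str
    cluster: int  # -1 for singletons
    true_neg_log10: float
    in_a: bool
    in_b: bool
    satellite: bool = False
    fingerprint: frozenset = field(repr=False, default=frozenset())


def _build_cluster(
    cluster_id: int, scaffold: str, spec: SyntheticSpec, rng: np.random.Generator
) -> list[SyntheticCompound]:
    """Pick substituents for one cluster until the similarity floor holds."""
    base = float(rng.uniform(*spec.activity_range))
    for _ in range(spec.max_retries):
        subs = rng.choice(len(SUBSTITUENTS), size=spec.cluster_size, replace=False)
        members = []
        for s in subs:
            smiles = scaffold.format(SUBSTITUENTS[s])
            structure = canonicalize(smiles)
            effect = float(rng.normal(0.0, spec.substituent_effect_sd))
            members.append(
                SyntheticCompound(
                    smiles=smiles,
                    canonical_smiles=structure.canonical_smiles,
                    cluster=cluster_id,
                    true_neg_log10=base + effect,
                    in_a=False,
                    in_b=False,
                    fingerprint=structure.fingerprint,
                )
            )
        min_sim = min(
            (
                tanimoto(m1.fingerprint, m2.fingerprint)
                for i, m1 in enumerate(members)
                for m2 in members[i + 1 :]
            ),
            default=1.0,
        )
        if min_sim >= spec.cluster_similarity_floor:
            members.extend(_build_satellites(cluster_id, scaffold, base, members, spec, rng))
            return members
    raise GenerationError(
        f"within-cluster similarity floor {spec.cluster_similarity_floor} "
        f"unsatisfiable for scaffold {scaffold!r} after {spec.max_retries} retries"
    )


def _build_satellites(
    cluster_id: int,
    scaffold: str,
    base: float,
    members: list[SyntheticCompound],
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> list[SyntheticCompound]:
    """Mid-similarity analogs of one cluster.

    A satellite shares the cluster's scaffold but carries a bulky
    substituent, placing it in the similarity band
    [singleton ceiling, cluster floor) relative to every regular member —
    reachable only at the lowered threshold, hence predicted with a warning.
    Its activity offset from the cluster base is drawn with a larger SD than
    a regular member's, reflecting the weaker structure–activity fidelity of
    more distant analogs.  Candidates are verified against the band and the
    satellites are drawn from the verified set.
    """
    if spec.n_satellites == 0:
        return []
    usable = []
    for big in SATELLITE_SUBSTITUENTS:
        smiles = scaffold.format(big)
        structure = canonicalize(smiles)
        sims = [tanimoto(structure.fingerprint, m.fingerprint) for m in members]
        if min(sims) >= spec.singleton_similarity_ceiling and max(sims) < spec.cluster_similarity_floor:
            usable.append((smiles, structure))
    if len(usable) < spec.n_satellites:
        raise GenerationError(
            f"satellite similarity band [{spec.singleton_similarity_ceiling}, "
            f"{spec.cluster_similarity_floor}) satisfiable for only {len(usable)} "
            f"of {spec.n_satellites} satellites of scaffold {scaffold!r}"
        )
    picks = rng.choice(len(usable), size=spec.n_satellites, replace=False)
    satellites = []
    for k in picks:
        smiles, structure = usable[k]
        satellites.append(
            SyntheticCompound(
                smiles=smiles,
                canonical_smiles=structure.canonical_smiles,
                cluster=cluster_id,
                true_neg_log10=base + float(rng.normal(0.0, spec.satellite_effect_sd)),
                in_a=False,
                in_b=False,
                satellite=True,
                fingerprint=structure.fingerprint,
            )
        )
    return satellites


def _pick_singletons(
    compounds: list[SyntheticCompound], spec: SyntheticSpec, rng: np.random.Generator
) -> list[SyntheticCompound]:
    pool = list(SINGLETON_POOL)
    rng.shuffle(pool)
    chosen: list[SyntheticCompound] = []
    for smiles in pool:
        if len(chosen) == spec.n_singletons:
            break
        structure = canonicalize(smiles)
        others = compounds + chosen
        max_sim = max(
            (tanimoto(structure.fingerprint, o.fingerprint) for o in others),
            default=0.0,
        )
        if max_sim < spec.singleton_similarity_ceiling:
            chosen.append(
                SyntheticCompound(
                    smiles=smiles,
                    canonical_smiles=structure.canonical_smiles,
                    cluster=-1,
                    true_neg_log10=float(rng.uniform(*spec.activity_range)),
                    in_a=False,
                    in_b=False,
                    fingerprint=structure.fingerprint,
                )
            )
    if len(chosen) < spec.n_singletons:
        raise GenerationError(
            f"singleton isolation constraint (max similarity < "
            f"{spec.singleton_similarity_ceiling}) satisfiable for only "
            f"{len(chosen)} of {spec.n_singletons} requested singletons"
        )
    return chosen


def _replicate_count(spec: SyntheticSpec, rng: np.random.Generator) -> int:
    n = int(min(rng.geometric(spec.replicate_geometric_p), spec.max_replicates))
    return max(spec.min_replicates, n)


def generate(spec: SyntheticSpec) -> tuple[ToxDataset, ToxDataset, pd.DataFrame]:
    """Generate the two synthetic databases and their ground-truth table.

    Returns preprocessed :class:`~readacross.data.ToxDataset` instances
    (sources "synthetic-a" and "synthetic-b") plus a DataFrame with one row
    per compound: SMILES, cluster label (-1 for singletons), true -log10
    LOAEL and database membership.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    compounds: list[SyntheticCompound] = []
    for c in range(spec.n_clusters):
        compounds.extend(_build_cluster(c, SCAFFOLDS[c], spec, rng))
    compounds.extend(_pick_singletons(compounds, spec, rng))
    seen = set()
    for comp in compounds:
        if comp.canonical_smiles in seen:
            raise GenerationError(f"duplicate structure generated: {comp.smiles!r}")
        seen.add(comp.canonical_smiles)

    # database membership: a stated fraction in both, the rest split evenly
    for comp in compounds:
        u = rng.random()
        if u < spec.both_db_fraction:
            comp.in_a = comp.in_b = True
        elif u < spec.both_db_fraction + (1 - spec.both_db_fraction) / 2:
            comp.in_a = True
        else:
            comp.in_b = True

    rows_a: list[tuple[str, float]] = []
    rows_b: list[tuple[str, float]] = []
    for comp in compounds:
        for present, rows in ((comp.in_a, rows_a), (comp.in_b, rows_b)):
            if not present:
                continue
            for _ in range(_replicate_count(spec, rng)):
                observed = comp.true_neg_log10 + float(rng.normal(0.0, spec.noise_sd_log))
                rows.append((comp.smiles, 10.0 ** (-observed)))

    db_a = dataset_from_records("synthetic-a", rows_a, unit="mmol/kg_bw/day")
    db_b = dataset_from_records("synthetic-b", rows_b, unit="mmol/kg_bw/day")
    truth = pd.DataFrame(
        {
            "smiles": [c.smiles for c in compounds],
            "canonical_smiles": [c.canonical_smiles for c in compounds],
            "cluster": [c.cluster for c in compounds],
            "satellite": [c.satellite for c in compounds],
            "true_neg_log10": [c.true_neg_log10 for c in compounds],
            "in_a": [c.in_a for c in compounds],
            "in_b": [c.in_b for c in compounds],
        }
    )
    return db_a, db_b, truth


def write_fixture_csvs(spec: SyntheticSpec, out_dir) -> dict[str, Path]:
    """Emit the generated databases in the CSV layout the reader expects.

    Same seed, same bytes: file content is fully determined by the parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db_a, db_b, truth = generate(spec)
    paths = {}
    for label, db in (("a", db_a), ("b", db_b)):
        frame = pd.DataFrame(
            {
                "smiles": [r.structure.input_smiles for r in db.records],
                "loael_mmol_kg_bw_day": [f"{r.original_value:.6e}" for r in db.records],
            }
        )
        path = out / f"synthetic_{label}.csv"
        frame.to_csv(path, index=False)
        paths[label] = path
    truth_path = out / "synthetic_truth.csv"
    truth.to_csv(truth_path, index=False, float_format="%.6e")
    paths["truth"] = truth_path
    return paths
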