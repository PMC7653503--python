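"""Synthetic cohorts, Ct matrices, networks and gene sets with planted truth.

Every generator is a pure function of its inputs and a seed, so each
downstream stage (normalization, differential expression, biomarker
evaluation, network propagation) can be exercised against known ground truth
without any external download.

The default cohort designs mirror the study layout this pipeline targets:

* a discovery cohort of 4 adult groups x 6 subjects (healthy control, mild
  asthma, severe asthma, COPD) profiled on a 96-well inflammation/autoimmunity
  lncRNA array (84 targets, 5 housekeeping genes, 1 genomic-DNA control,
  3 reverse-transcription controls, 3 positive PCR controls);
* a replication cohort of 163 subjects in 6 groups (childhood control n=16,
  childhood asthma n=11, adult control n=7, adult asthma n=95, COPD n=9,
  allergic rhinitis n=25) measured for 6 lncRNAs against 2 reference genes
  (B2M, RPLP0) in technical duplicate.

Effects are planted on the cycle scale with a minus sign (higher expression
means a lower threshold cycle), so a planted log2 fold change of ``x`` equals
the group difference of ``-delta_ct`` by construction.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .funcpred import GeneSetCollection
from .normalization import CT_MAX, CT_MIN, CtMatrix

# ---------------------------------------------------------------------------
# cohort designs
# ---------------------------------------------------------------------------


@dataclass
class GroupSpec:
    label: str
    n_samples: int
    age_class: str = "adult"  # child | adult
    allergy_fraction: float = 0.0
    severity: str | None = None


@dataclass
class CohortDesign:
    groups: list[GroupSpec]
    sex_balance: float = 0.5  # fraction male
    cohort_id: str = "cohort"

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort design needs at least one group")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError(f"group labels not unique: {labels}")
        for g in self.groups:
            if g.n_samples < 1:
                raise ValueError(f"group {g.label!r} has n_samples < 1")
            if not 0 <= g.allergy_fraction <= 1:
                raise ValueError(f"allergy_fraction outside [0,1] in {g.label!r}")
            if g.age_class not in ("child", "adult"):
                raise ValueError(f"unknown age_class {g.age_class!r}")
        if not 0 <= self.sex_balance <= 1:
            raise ValueError("sex_balance outside [0,1]")

    @property
    def n_total(self) -> int:
        return sum(g.n_samples for g in self.groups)


def discovery_design() -> CohortDesign:
    """4 adult groups x 6 subjects; 9/24 male overall."""
    return CohortDesign(
        groups=[
            GroupSpec("control", 6),
            GroupSpec("mild_asthma", 6, allergy_fraction=0.5, severity="mild"),
            GroupSpec("severe_asthma", 6, allergy_fraction=5 / 6, severity="severe"),
            GroupSpec("copd", 6, allergy_fraction=1 / 6),
        ],
        sex_balance=9 / 24,
        cohort_id="discovery",
    )


def replication_design() -> CohortDesign:
    """6 groups, n = 16/11/7/95/9/25 (163 subjects); 73/163 male overall."""
    return CohortDesign(
        groups=[
            GroupSpec("childhood_control", 16, age_class="child"),
            GroupSpec("childhood_asthma", 11, age_class="child",
                      allergy_fraction=10 / 11, severity="mild"),
            GroupSpec("adult_control", 7),
            GroupSpec("adult_asthma", 95, allergy_fraction=74 / 95),
            GroupSpec("copd", 9, allergy_fraction=3 / 9),
            GroupSpec("allergic_rhinitis", 25, allergy_fraction=1.0),
        ],
        sex_balance=73 / 163,
        cohort_id="replication",
    )


def generate_cohort_metadata(design: CohortDesign, seed: int) -> pd.DataFrame:
    """One row per sample: sample_id, group, age_class, sex, allergic, severity.

    Group sizes are exact; sex counts are the rounded cohort-level fraction,
    assigned to samples by a seeded permutation; allergy status is assigned
    per group the same way.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in design.groups:
        allergic = np.zeros(g.n_samples, dtype=bool)
        allergic[: round(g.allergy_fraction * g.n_samples)] = True
        rng.shuffle(allergic)
        for i in range(g.n_samples):
            rows.append(
                {
                    "sample_id": f"{design.cohort_id}_{g.label}_{i + 1:03d}",
                    "group": g.label,
                    "age_class": g.age_class,
                    "allergic": bool(allergic[i]),
                    "severity": g.severity if g.severity is not None else "",
                }
            )
    meta = pd.DataFrame(rows).set_index("sample_id")
    n = len(meta)
    sex = np.array(["female"] * n, dtype=object)
    sex[: round(design.sex_balance * n)] = "male"
    rng.shuffle(sex)
    meta["sex"] = sex
    return meta[["group", "age_class", "sex", "allergic", "severity"]]


# ---------------------------------------------------------------------------
# Ct matrices with planted effects
# ---------------------------------------------------------------------------


@dataclass
class EffectSpec:
    """Planted truth for the Ct generator, all on the cycle / log2 scale.

    ``group_log2fc[(feature, group)]`` is the planted log2 fold change of the
    group relative to the implicit baseline (a group absent from the map);
    ``sex_log2fc`` applies to males, ``age_log2fc`` to children.
    """

    baseline_delta_ct: dict[str, float]
    group_log2fc: dict[tuple[str, str], float] = field(default_factory=dict)
    sex_log2fc: dict[str, float] = field(default_factory=dict)
    age_log2fc: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.8
    reference_ct_mean: float = 20.0
    reference_ct_sd: float = 0.5
    dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.reference_ct_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob outside [0,1]")
        orphans = {f for f, _ in self.group_log2fc} - set(self.baseline_delta_ct)
        if orphans:
            raise ValueError(
                f"group_log2fc features missing from baseline_delta_ct: {orphans}"
            )


def generate_ct_matrix(
    metadata: pd.DataFrame,
    effects: EffectSpec,
    feature_roles: dict[str, str],
    seed: int,
    duplicates: bool = False,
) -> CtMatrix:
    """Simulate a Ct matrix over ``metadata``'s samples.

    Target wells: ``Ct = reference_ct_mean + baseline_delta_ct[f]
    - (group + sex + age log2FC terms) + N(0, noise_sd)``.  Housekeeping and
    control wells are drawn around ``reference_ct_mean`` with
    ``reference_ct_sd``.  Draws outside [0, 40] are clipped and counted on the
    returned matrix.  With ``duplicates=True`` each well is emitted twice
    (suffixes ``__r1``/``__r2``) with independent noise and a ``replicate_of``
    map, emulating duplicate measurement.
    """
    if not any(r == "housekeeping" for r in feature_roles.values()):
        raise ValueError("feature_roles must include at least one housekeeping gene")
    rng = np.random.default_rng(seed)
    samples = metadata.index
    targets = [f for f, r in feature_roles.items() if r == "target"]
    others = [f for f in feature_roles if feature_roles[f] != "target"]

    effect = pd.DataFrame(0.0, index=targets, columns=samples)
    for f in targets:
        base = effects.baseline_delta_ct.get(f, 0.0)
        for s in samples:
            e = effects.group_log2fc.get((f, metadata.at[s, "group"]), 0.0)
            if metadata.at[s, "sex"] == "male":
                e += effects.sex_log2fc.get(f, 0.0)
            if metadata.at[s, "age_class"] == "child":
                e += effects.age_log2fc.get(f, 0.0)
            effect.at[f, s] = effects.reference_ct_mean + base - e

    n_rep = 2 if duplicates else 1
    frames, roles, replicate_of = [], {}, {}
    for rep in range(1, n_rep + 1):
        tgt = effect + rng.normal(0.0, effects.noise_sd, size=effect.shape)
        hk = pd.DataFrame(
            rng.normal(
                effects.reference_ct_mean,
                effects.reference_ct_sd,
                size=(len(others), len(samples)),
            ),
            index=others,
            columns=samples,
        )
        block = pd.concat([tgt, hk])
        if duplicates:
            new_index = [f"{f}__r{rep}" for f in block.index]
            for old, new in zip(block.index, new_index):
                replicate_of[new] = old
                roles[new] = feature_roles[old]
            block.index = new_index
        else:
            roles.update({f: feature_roles[f] for f in block.index})
        frames.append(block)
    ct = pd.concat(frames)

    vals = ct.to_numpy()
    n_clipped = int(np.sum((vals < CT_MIN) | (vals > CT_MAX)))
    ct = ct.clip(lower=CT_MIN, upper=CT_MAX)
    if effects.dropout_prob > 0:
        mask = rng.random(ct.shape) < effects.dropout_prob
        ct = ct.mask(mask)
    return CtMatrix(
        ct=ct,
        feature_roles=roles,
        replicate_of=replicate_of if duplicates else None,
        n_clipped=n_clipped,
    )


# --- default study fixtures -------------------------------------------------

REPLICATION_LNCRNAS = [
    "OIP5-AS1", "JPX", "HNRNPU", "RP11-325K4.3", "RP11-282O18.3", "MZF1-AS1",
]
REPLICATION_REFERENCES = ["B2M", "RPLP0"]
DISCOVERY_REFERENCES = ["SNORA73A", "RN7SK", "RPLP0", "B2M", "ACTB"]


def discovery_feature_roles(n_targets: int = 84) -> dict[str, str]:
    """96-well array layout: 84 targets, 5 housekeeping, 1 gDNA, 3 RT, 3 PPC."""
    roles: dict[str, str] = {}
    named = ["XIST", "NAV2-AS5"] + REPLICATION_LNCRNAS
    for i in range(n_targets):
        name = named[i] if i < len(named) else f"LNC{i + 1:03d}"
        roles[name] = "target"
    for hk in DISCOVERY_REFERENCES:
        roles[hk] = "housekeeping"
    roles["HGDC"] = "gdna_control"
    for i in range(1, 4):
        roles[f"RTC{i}"] = "rt_control"
    for i in range(1, 4):
        roles[f"PPC{i}"] = "ppc_control"
    return roles


def replication_feature_roles() -> dict[str, str]:
    roles = {f: "target" for f in REPLICATION_LNCRNAS}
    roles.update({f: "housekeeping" for f in REPLICATION_REFERENCES})
    return roles


def replication_effects(noise_sd: float = 0.8) -> EffectSpec:
    """Planted truth for the default replication cohort.

    Group effects are expressed relative to the adult control baseline and
    emulate the magnitudes of the reported fold changes: allergic rhinitis
    elevated by ~0.7-1.2 log2 units on all six lncRNAs, and three lncRNAs
    (HNRNPU, RP11-325K4.3, JPX) elevated in children.
    """
    baseline = {f: 5.0 for f in REPLICATION_LNCRNAS}
    ar = {
        "OIP5-AS1": 1.11, "JPX": 1.17, "RP11-325K4.3": 1.18,
        "HNRNPU": 1.10, "RP11-282O18.3": 1.11, "MZF1-AS1": 0.74,
    }
    group_fc: dict[tuple[str, str], float] = {}
    for f, v in ar.items():
        group_fc[(f, "allergic_rhinitis")] = v
    # COPD sits below rhinitis by the rhinitis-vs-COPD contrasts
    for f, v in {"RP11-325K4.3": -0.2, "OIP5-AS1": 0.28, "JPX": 0.24,
                 "HNRNPU": 0.38, "MZF1-AS1": -0.17}.items():
        group_fc[(f, "copd")] = v
    for f, v in {"OIP5-AS1": 0.55, "HNRNPU": 0.67, "RP11-325K4.3": 0.49,
                 "RP11-282O18.3": 0.57, "JPX": 0.73}.items():
        group_fc[(f, "adult_asthma")] = v
    age = {"HNRNPU": 1.01, "RP11-325K4.3": 0.96, "JPX": 0.85}
    return EffectSpec(
        baseline_delta_ct=baseline,
        group_log2fc=group_fc,
        age_log2fc=age,
        noise_sd=noise_sd,
    )


def discovery_effects(noise_sd: float = 0.8, seed: int = 0) -> EffectSpec:
    """Planted truth for the default discovery array: severity-graded effects
    on a handful of lncRNAs plus two sex-dimorphic features (an XIST analog
    expressed higher in females, a testis lncRNA analog higher in males)."""
    roles = discovery_feature_roles()
    targets = [f for f, r in roles.items() if r == "target"]
    rng = np.random.default_rng(seed)
    baseline = {f: float(rng.uniform(3.0, 8.0)) for f in targets}
    group_fc: dict[tuple[str, str], float] = {}
    for f in REPLICATION_LNCRNAS:
        group_fc[(f, "severe_asthma")] = 1.2
        group_fc[(f, "mild_asthma")] = 0.6
        group_fc[(f, "copd")] = 0.3
    sex = {"XIST": -3.0, "NAV2-AS5": 2.5}
    return EffectSpec(
        baseline_delta_ct=baseline,
        group_log2fc=group_fc,
        sex_log2fc=sex,
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# network fixtures
# ---------------------------------------------------------------------------


@dataclass
class NetworkFixtureSpec:
    n_lnc: int = 6
    n_genes: int = 100
    n_samples: int = 30
    n_validated_targets: int = 20
    ppi_density: float = 0.05
    planted_module: tuple[str, list[str]] | None = None
    similarity_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ppi_density <= 1:
            raise ValueError("ppi_density outside [0,1]")
        if self.similarity_noise_sd < 0:
            raise ValueError("similarity_noise_sd must be non-negative")
        if self.planted_module is not None:
            lnc, genes = self.planted_module
            universe = {f"G{i + 1:04d}" for i in range(self.n_genes)}
            lncs = {f"LNC{i + 1:03d}" for i in range(self.n_lnc)}
            if lnc not in lncs:
                raise ValueError(f"planted lncRNA {lnc!r} outside universe")
            outside = set(genes) - universe
            if outside:
                raise ValueError(f"planted genes outside universe: {outside}")


def generate_network_fixture(
    spec: NetworkFixtureSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression matrices and edge lists for the heterogeneous network.

    Returns ``(lnc_expr, gene_expr, target_edges, ppi_edges)``.  The planted
    module's lncRNA and genes share one latent expression signal plus Gaussian
    noise of sd ``similarity_noise_sd`` (perfectly correlated at sd 0), and
    the planted lncRNA-gene pairs head the validated-target edge list.
    """
    rng = np.random.default_rng(spec.seed)
    lncs = [f"LNC{i + 1:03d}" for i in range(spec.n_lnc)]
    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    samples = [f"S{i + 1:03d}" for i in range(spec.n_samples)]

    lnc_expr = pd.DataFrame(
        rng.normal(size=(spec.n_lnc, spec.n_samples)), index=lncs, columns=samples
    )
    gene_expr = pd.DataFrame(
        rng.normal(size=(spec.n_genes, spec.n_samples)), index=genes, columns=samples
    )
    planted_pairs: list[tuple[str, str]] = []
    if spec.planted_module is not None:
        lnc, module_genes = spec.planted_module
        signal = rng.normal(size=spec.n_samples)
        lnc_expr.loc[lnc] = signal
        for g in module_genes:
            gene_expr.loc[g] = signal + rng.normal(
                0.0, spec.similarity_noise_sd, size=spec.n_samples
            )
            planted_pairs.append((lnc, g))

    pairs = planted_pairs[: spec.n_validated_targets]
    remaining = spec.n_validated_targets - len(pairs)
    if remaining > 0:
        pool = [
            (l, g) for l in lncs for g in genes if (l, g) not in set(planted_pairs)
        ]
        idx = rng.choice(len(pool), size=remaining, replace=False)
        pairs += [pool[i] for i in sorted(idx)]
    target_edges = pd.DataFrame(pairs, columns=["node_a", "node_b"])
    target_edges["weight"] = 1.0

    all_gene_pairs = list(itertools.combinations(genes, 2))
    keep = rng.random(len(all_gene_pairs)) < spec.ppi_density
    ppi_edges = pd.DataFrame(
        [p for p, k in zip(all_gene_pairs, keep) if k], columns=["node_a", "node_b"]
    )
    ppi_edges["weight"] = 1.0
    return lnc_expr, gene_expr, target_edges, ppi_edges


def generate_gene_sets(
    gene_universe: list[str],
    n_sets: int,
    set_size_range: tuple[int, int],
    planted_set: list[str] | None = None,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets (sampled without replacement within each set), with an
    optional planted set included verbatim as ``planted``."""
    lo, hi = set_size_range
    if lo < 2:
        raise ValueError("set sizes must be >= 2")
    if hi > len(gene_universe):
        raise ValueError("set size exceeds universe size")
    if planted_set is not None:
        outside = set(planted_set) - set(gene_universe)
        if outside:
            raise ValueError(f"planted genes outside universe: {outside}")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    if planted_set is not None:
        sets["planted"] = list(planted_set)
        descriptions["planted"] = "planted module"
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_universe, size=size, replace=False)
        name = f"random_set_{i + 1:03d}"
        sets[name] = sorted(members.tolist())
        descriptions[name] = "random set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_fixture(
    outdir: str | Path,
    metadata: pd.DataFrame,
    ct: CtMatrix,
    seed: int,
) -> dict[str, str]:
    """Write metadata/Ct/roles as TSV plus a JSON seed sidecar; returns paths."""
    from .normalization import write_ct_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": str(outdir / "metadata.tsv"),
        "ct": str(outdir / "ct.tsv"),
        "roles": str(outdir / "roles.tsv"),
        "seeds": str(outdir / "seeds.json"),
    }
    metadata.to_csv(paths["metadata"], sep="\t")
    write_ct_table(ct, paths["ct"], paths["roles"])
    with open(paths["seeds"], "w") as fh:
        json.dump({"seed": seed, "n_clipped": ct.n_clipped}, fh, indent=2)
    return paths
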