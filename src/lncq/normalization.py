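"""Ct-table handling, quality control and delta-Ct normalization.

qPCR quantification in this pipeline follows the comparative-Ct convention:
for each sample the arithmetic mean of the housekeeping (reference) gene
threshold cycles is subtracted from every target threshold cycle, giving
``delta_ct = Ct(target) - mean(Ct(references))``, and relative expression is
``2 ** -delta_ct``.  Cycles are the measurement scale throughout: technical
replicates are averaged on the Ct scale, and all QC rules operate on cycles.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("lncq")

#: Valid feature roles on a qPCR plate.
ROLES = ("target", "housekeeping", "gdna_control", "rt_control", "ppc_control")

CT_MIN = 0.0
CT_MAX = 40.0


@dataclass
class CtMatrix:
    """Raw threshold-cycle values, features x samples.

    Parameters
    ----------
    ct
        DataFrame of cycles in [0, 40]; NaN marks undetermined wells.
    feature_roles
        Maps every feature id to one of :data:`ROLES`.
    replicate_of
        Optional map from replicate-well feature id to its canonical feature
        id; wells sharing a canonical id are technical replicates.
    n_clipped
        Number of simulated draws that fell outside [0, 40] and were clipped
        (0 for measured data).
    """

    ct: pd.DataFrame
    feature_roles: dict[str, str]
    replicate_of: dict[str, str] | None = None
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if self.ct.index.duplicated().any():
            dups = self.ct.index[self.ct.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        missing_roles = [f for f in self.ct.index if f not in self.feature_roles]
        if missing_roles:
            raise ValueError(f"no role assigned for features: {missing_roles}")
        bad_roles = {f: r for f, r in self.feature_roles.items() if r not in ROLES}
        if bad_roles:
            raise ValueError(f"unknown roles: {bad_roles}")
        vals = self.ct.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out_of_range = np.nansum((vals < CT_MIN) | (vals > CT_MAX))
        if out_of_range:
            raise ValueError(f"{int(out_of_range)} Ct values outside [0, 40]")

    @property
    def features(self) -> pd.Index:
        return self.ct.index

    @property
    def samples(self) -> pd.Index:
        return self.ct.columns

    def features_with_role(self, role: str) -> list[str]:
        return [f for f in self.ct.index if self.feature_roles[f] == role]


@dataclass
class DeltaCtMatrix:
    """delta-Ct values (target features x samples) and the reference panel."""

    delta_ct: pd.DataFrame
    reference_features: list[str]
    reference_mean: pd.Series  # per-sample mean reference Ct


@dataclass
class ExpressionMatrix:
    """Normalized expression: ``expr = 2**-delta_ct``, ``log2_expr = -delta_ct``."""

    expr: pd.DataFrame
    log2_expr: pd.DataFrame


@dataclass
class QCRules:
    """Per-sample exclusion criteria, on the cycle scale.

    ``gdna_ct_min``: a genomic-DNA-contamination control amplifying *earlier*
    (lower Ct) than this bound indicates contamination and fails the sample.
    """

    missingness_max: float = 0.5
    gdna_ct_min: float = 35.0
    replicate_max_discordance: float = 1.0


@dataclass
class QCReport:
    excluded: dict[str, str] = field(default_factory=dict)  # sample -> rule text
    flags: list[str] = field(default_factory=list)
    n_replicate_pairs_collapsed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "excluded": self.excluded,
                "flags": self.flags,
                "n_replicate_pairs_collapsed": self.n_replicate_pairs_collapsed,
            },
            indent=2,
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_ct_table(path: str | Path, role_map_path: str | Path) -> CtMatrix:
    """Read a Ct table (features x samples, first column feature ids) plus a
    two-column role map.  Comma/tab dialect is auto-detected."""
    path, role_map_path = Path(path), Path(role_map_path)
    delim = _sniff_delimiter(path)
    logger.info("reading %s (delimiter=%r)", path, delim)
    ct = pd.read_csv(path, sep=delim, index_col=0)
    if ct.index.duplicated().any():
        dups = ct.index[ct.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {path}: {dups}")
    roles_df = pd.read_csv(role_map_path, sep=_sniff_delimiter(role_map_path))
    roles = dict(zip(roles_df.iloc[:, 0], roles_df.iloc[:, 1]))
    return CtMatrix(ct=ct.astype(float), feature_roles=roles)


def write_ct_table(ct: CtMatrix, path: str | Path, role_map_path: str | Path) -> None:
    ct.ct.to_csv(path, sep="\t", index_label="feature")
    pd.DataFrame(
        {"feature": list(ct.feature_roles), "role": list(ct.feature_roles.values())}
    ).to_csv(role_map_path, sep="\t", index=False)


def collapse_replicates(
    ct: CtMatrix, max_discordance: float = 1.0
) -> tuple[CtMatrix, list[str], int]:
    """Average technical replicate wells on the Ct scale.

    Returns the collapsed matrix, discordance flags (pairs disagreeing by more
    than ``max_discordance`` cycles in some sample) and the number of
    replicate groups collapsed.
    """
    if not ct.replicate_of:
        return ct, [], 0
    canonical = {f: ct.replicate_of.get(f, f) for f in ct.ct.index}
    groups: dict[str, list[str]] = {}
    for well, canon in canonical.items():
        groups.setdefault(canon, []).append(well)
    rows, flags, n_collapsed = {}, [], 0
    roles = {}
    for canon, wells in groups.items():
        sub = ct.ct.loc[wells]
        if len(wells) > 1:
            n_collapsed += 1
            spread = sub.max(axis=0) - sub.min(axis=0)
            for smp in spread.index[spread > max_discordance]:
                flags.append(
                    f"replicate discordance {spread[smp]:.2f} cycles for "
                    f"{canon} in sample {smp}"
                )
        rows[canon] = sub.mean(axis=0, skipna=True)
        roles[canon] = ct.feature_roles[wells[0]]
    collapsed = pd.DataFrame(rows).T
    collapsed = collapsed.loc[list(groups)]
    return (
        CtMatrix(ct=collapsed, feature_roles=roles, n_clipped=ct.n_clipped),
        flags,
        n_collapsed,
    )


def qc_filter(ct: CtMatrix, rules: QCRules | None = None) -> tuple[CtMatrix, QCReport]:
    """Collapse technical duplicates, then drop samples failing QC.

    Exclusion rules: fraction of missing target wells above
    ``missingness_max``; genomic-DNA control Ct below ``gdna_ct_min``.
    Replicate discordance beyond ``replicate_max_discordance`` cycles is
    flagged but does not exclude.
    """
    rules = rules or QCRules()
    report = QCReport()
    ct, flags, n_collapsed = collapse_replicates(ct, rules.replicate_max_discordance)
    report.flags.extend(flags)
    report.n_replicate_pairs_collapsed = n_collapsed

    targets = ct.features_with_role("target")
    gdna = ct.features_with_role("gdna_control")
    for sample in ct.samples:
        if targets:
            miss = ct.ct.loc[targets, sample].isna().mean()
            if miss > rules.missingness_max:
                report.excluded[sample] = (
                    f"target missingness {miss:.2f} > {rules.missingness_max}"
                )
                continue
        for g in gdna:
            val = ct.ct.loc[g, sample]
            if pd.notna(val) and val < rules.gdna_ct_min:
                report.excluded[sample] = (
                    f"gDNA control {g} Ct {val:.2f} < {rules.gdna_ct_min} "
                    "(contamination)"
                )
                break
    keep = [s for s in ct.samples if s not in report.excluded]
    if not keep:
        raise ValueError("QC excluded every sample")
    if report.excluded:
        logger.info("QC excluded %d sample(s): %s", len(report.excluded), report.excluded)
    filtered = CtMatrix(
        ct=ct.ct[keep],
        feature_roles=ct.feature_roles,
        replicate_of=None,
        n_clipped=ct.n_clipped,
    )
    return filtered, report


def delta_ct(ct: CtMatrix, reference_features: list[str]) -> DeltaCtMatrix:
    """Subtract the per-sample arithmetic mean of the reference-gene Ct values
    from every target Ct."""
    for ref in reference_features:
        if ref not in ct.ct.index:
            raise ValueError(f"reference feature {ref!r} not in matrix")
        if ct.feature_roles[ref] != "housekeeping":
            raise ValueError(f"reference feature {ref!r} has role "
                             f"{ct.feature_roles[ref]!r}, expected housekeeping")
    ref_ct = ct.ct.loc[reference_features]
    n_usable = ref_ct.notna().sum(axis=0)
    bad = n_usable.index[n_usable == 0].tolist()
    if bad:
        raise ValueError(f"samples with no usable reference Ct: {bad}")
    reference_mean = ref_ct.mean(axis=0, skipna=True)
    targets = ct.features_with_role("target")
    dct = ct.ct.loc[targets].sub(reference_mean, axis=1)
    return DeltaCtMatrix(
        delta_ct=dct,
        reference_features=list(reference_features),
        reference_mean=reference_mean,
    )


def normalize_expression(d: DeltaCtMatrix) -> ExpressionMatrix:
    """``expr = 2**-delta_ct``; missing values propagate."""
    log2_expr = -d.delta_ct
    expr = np.power(2.0, log2_expr)
    return ExpressionMatrix(expr=expr, log2_expr=log2_expr)
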