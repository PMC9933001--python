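"""Paired confound statistics and QC filters.

MAPE (mean absolute percentage error) is the paired variability measure:
the absolute difference divided by the pair mean, ×100.  MPV (mean
percent variation) is its signed version, used to detect systematic bias
between conditions.  Confound effects are compared with paired Wilcoxon
signed-rank tests, Bonferroni-corrected over the number of comparisons
actually performed.

QC removes a bundle when its streamline count falls more than 3 SD below
the pathway mean or under 200 streamlines (tractography failure), and
removes a subject from a method when more than 20% of its pathways fail.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

QC_MIN_STREAMLINES = 200
QC_SD_FACTOR = 3.0
QC_SUBJECT_FRACTION = 0.20
DEFAULT_ALPHA = 0.05


def mape(x1: float, x2: float) -> float:
    """Absolute percent difference relative to the pair mean: 100·|Δ|/mean."""
    m = (x1 + x2) / 2.0
    if m == 0:
        raise ValueError("MAPE undefined: pair mean is zero")
    return 100.0 * abs(x1 - x2) / abs(m)


def mpv(x_ref: float, x_other: float) -> float:
    """Signed MAPE, oriented (other − reference); |mpv| == mape."""
    m = (x_ref + x_other) / 2.0
    if m == 0:
        raise ValueError("MPV undefined: pair mean is zero")
    return 100.0 * (x_other - x_ref) / abs(m)


@dataclass
class WilcoxonResult:
    """All-pairs confound comparison with Bonferroni correction."""

    p_values: pd.DataFrame  # square, NaN where skipped
    significant: pd.DataFrame  # boolean at the corrected threshold
    n_tests: int
    alpha: float
    alpha_corrected: float
    skipped: list[tuple[str, str, str]] = field(default_factory=list)


def paired_wilcoxon(
    groups: Mapping[str, Mapping[str, float] | pd.Series],
    alpha: float = DEFAULT_ALPHA,
    n_methods: int = 1,
    n_tests: Optional[int] = None,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank tests between every confound pair.

    ``groups`` maps a confound id to its per-subject values; pairs are
    matched on the shared subject keys.  Comparisons with fewer than 3
    common subjects are skipped.  Zero differences are dropped
    (Wilcoxon's original treatment); the correction divides ``alpha`` by
    the number of tests actually run times ``n_methods`` (per the
    p < .05 / n_pairs / n_methods convention), unless ``n_tests``
    overrides the count.
    """
    names = list(groups)
    series = {k: pd.Series(dict(v) if isinstance(v, Mapping) else v) for k, v in groups.items()}
    p = pd.DataFrame(np.nan, index=names, columns=names)
    skipped: list[tuple[str, str, str]] = []
    n_run = 0
    for a, b in itertools.combinations(names, 2):
        common = series[a].index.intersection(series[b].index)
        if len(common) < 3:
            skipped.append((a, b, f"only {len(common)} common subjects"))
            continue
        d = (series[a][common] - series[b][common]).to_numpy(dtype=float)
        if np.all(d == 0):
            pval = 1.0  # no signal at all
        else:
            pval = float(
                stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="auto").pvalue
            )
        p.loc[a, b] = p.loc[b, a] = pval
        n_run += 1
    total = n_tests if n_tests is not None else n_run * n_methods
    alpha_corr = alpha / total if total > 0 else alpha
    return WilcoxonResult(
        p_values=p,
        significant=p < alpha_corr,
        n_tests=total,
        alpha=alpha,
        alpha_corrected=alpha_corr,
        skipped=skipped,
    )


@dataclass
class QCReport:
    removed_bundles: list[tuple[str, str, str, str]]  # subject, dataset, pathway, reason
    removed_subjects: list[tuple[str, str, float]]  # subject, method, fraction failed

    def bundle_removed(self, subject: str, dataset: str, pathway: str) -> bool:
        return any(
            (s, d, p) == (subject, dataset, pathway) for s, d, p, _ in self.removed_bundles
        )

    def subject_removed(self, subject: str, method: str = "all") -> bool:
        return any((s, m) == (subject, method) for s, m, _ in self.removed_subjects)


def qc_filter(
    counts: pd.DataFrame,
    min_streamlines: int = QC_MIN_STREAMLINES,
    sd_factor: float = QC_SD_FACTOR,
    subject_fraction: float = QC_SUBJECT_FRACTION,
    manual_exclusions: Optional[Sequence[tuple[str, str, str]]] = None,
) -> QCReport:
    """Apply the streamline-count QC rules to a long-format count table.

    ``counts`` needs columns ``subject``, ``dataset``, ``pathway``,
    ``n_streamlines`` and optionally ``method`` (defaults to a single
    method).  A bundle fails when its count drops more than
    ``sd_factor`` SDs below its pathway mean, or below
    ``min_streamlines``; a subject is removed from a method when the
    failed fraction of its bundles exceeds ``subject_fraction``.
    ``manual_exclusions`` supplies (subject, dataset, pathway) triples
    from visual inspection; they are recorded with reason "manual".
    """
    df = counts.copy()
    if "method" not in df.columns:
        df["method"] = "all"
    removed: list[tuple[str, str, str, str]] = []
    manual = {tuple(x) for x in (manual_exclusions or [])}
    for (method, pathway), grp in df.groupby(["method", "pathway"], sort=True):
        vals = grp["n_streamlines"].to_numpy(dtype=float)
        mean = vals.mean()
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        low = mean - sd_factor * sd
        for _, row in grp.iterrows():
            key = (row["subject"], row["dataset"], row["pathway"])
            if key in manual:
                reason = "manual"
            elif len(vals) > 1 and row["n_streamlines"] < low:
                reason = f"count below pathway mean - {sd_factor:g} SD"
            elif row["n_streamlines"] < min_streamlines:
                reason = f"count below {min_streamlines}"
            else:
                continue
            removed.append((*key, reason))
    removed_set = {(s, d, p) for s, d, p, _ in removed}
    removed_subjects: list[tuple[str, str, float]] = []
    for (method, subject), grp in df.groupby(["method", "subject"], sort=True):
        keys = list(zip(grp["subject"], grp["dataset"], grp["pathway"]))
        frac = sum(k in removed_set for k in keys) / len(keys)
        if frac > subject_fraction:
            removed_subjects.append((subject, method, frac))
    return QCReport(removed_bundles=removed, removed_subjects=removed_subjects)
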