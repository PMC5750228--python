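"""Soil-water metabolite table handling and filtering.

Operations on LC/MS-style peak-area tables: sample QC, the two-fold
dynamic-range filter, per-metabolite row normalization, hierarchical
clustering of temporal profiles, PCA ordination of samples, and the
killed-control (active vs autoclaved biocrust) significance test that
separates biologically controlled metabolite dynamics from abiotic ones
(leaching, sorption, thermolysis).

Statistics are computed on log(1 + area); peak areas span decades and
multiplicative noise is roughly constant-CV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

META_COLUMNS = ("time", "stage", "replicate", "condition", "qc_pass")
CONDITIONS = ("active", "killed", "extraction_control")


@dataclass
class PeakAreaTable:
    """Metabolite x sample peak areas plus per-sample metadata.

    ``areas`` is a DataFrame indexed by metabolite id with one column
    per sample (NaN = missing/not detected). ``meta`` is indexed by
    sample id with columns time (h), stage, replicate, condition and
    qc_pass, in register with ``areas.columns``.
    """

    areas: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.areas.columns) != list(self.meta.index):
            raise ValueError("areas columns and meta index must match in order")
        if self.areas.index.has_duplicates or self.areas.columns.has_duplicates:
            raise ValueError("metabolite and sample labels must be unique")
        if (self.areas < 0).any().any():
            raise ValueError("negative peak areas")
        missing = set(META_COLUMNS) - set(self.meta.columns)
        if missing:
            raise ValueError(f"meta lacks columns: {sorted(missing)}")
        bad = set(self.meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    @property
    def metabolites(self) -> list[str]:
        return list(self.areas.index)

    @property
    def n_samples(self) -> int:
        return self.areas.shape[1]

    def subset_samples(self, sample_ids) -> "PeakAreaTable":
        ids = [s for s in self.areas.columns if s in set(sample_ids)]
        return PeakAreaTable(self.areas[ids], self.meta.loc[ids])

    def subset_metabolites(self, metabolite_ids) -> "PeakAreaTable":
        keep = [m for m in self.areas.index if m in set(metabolite_ids)]
        return PeakAreaTable(self.areas.loc[keep], self.meta)

    def cell_means(self) -> pd.DataFrame:
        """Per-(stage, time) mean over replicates, missing ignored.

        Returns a metabolite x MultiIndex(stage, time) DataFrame; cells
        with no non-missing replicate are NaN.
        """
        means = self.areas.T.groupby(
            [self.meta["stage"].to_numpy(), self.meta["time"].to_numpy()]
        ).mean()
        means.index.names = ["stage", "time"]
        return means.T.sort_index(axis=1)


def qc_filter(table: PeakAreaTable) -> PeakAreaTable:
    """Drop samples whose QC flag is False (e.g. internal standards
    missing from the expected retention-time window)."""
    if table.n_samples == 0:
        raise ValueError("empty peak-area table")
    failed = table.meta.index[~table.meta["qc_pass"].astype(bool)]
    for s in failed:
        logger.info("qc_filter: dropping sample %s (QC failed)", s)
    keep = [s for s in table.areas.columns if s not in set(failed)]
    if not keep:
        raise ValueError("qc_filter removed every sample")
    return table.subset_samples(keep)


def fold_range_filter(
    table: PeakAreaTable, threshold: float = 2.0
) -> tuple[list[str], list[str]]:
    """Two-fold dynamic-range filter on (stage, time) cell means.

    A metabolite is retained iff the ratio of its maximum cell mean to
    its minimum *positive* cell mean is >= ``threshold``. Metabolites
    with fewer than two non-missing cell means cannot be evaluated and
    are excluded (returned separately).

    Returns ``(retained_ids, unevaluable_ids)``.
    """
    means = table.cell_means()
    retained, unevaluable = [], []
    for m, row in means.iterrows():
        vals = row.dropna().to_numpy(dtype=float)
        if vals.size < 2:
            unevaluable.append(m)
            logger.info("fold_range_filter: %s unevaluable (<2 cells)", m)
            continue
        pos = vals[vals > 0]
        if pos.size == 0:
            unevaluable.append(m)
            continue
        if vals.max() / pos.min() >= threshold:
            retained.append(m)
        else:
            logger.info("fold_range_filter: %s excluded (range < %g-fold)", m, threshold)
    return retained, unevaluable


def row_normalize(means: pd.DataFrame) -> pd.DataFrame:
    """Scale each metabolite's cell-mean profile to its maximum.

    Output values lie in [0, 1] with at least one 1.0 per row; used for
    heatmap display and profile clustering.
    """
    out = means.copy().astype(float)
    for m, row in out.iterrows():
        vals = row.dropna()
        if vals.empty:
            raise ValueError(f"row_normalize: {m} is all-missing")
        mx = vals.max()
        if mx <= 0:
            raise ValueError(f"row_normalize: {m} has no positive value")
        out.loc[m] = row / mx
    return out


def cluster_metabolites(
    normalized: pd.DataFrame, k: int = 3
) -> tuple[pd.Series, list[str]]:
    """Agglomerative clustering of metabolite temporal profiles.

    Distance is correlation distance (1 - Pearson between profiles) with
    average linkage, cut into ``k`` flat clusters. Missing values are
    imputed with the row mean before computing distances. Returns the
    cluster label per metabolite (1..k) and the dendrogram leaf order.
    """
    n = normalized.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of metabolites ({n})")
    x = normalized.to_numpy(dtype=float)
    rowmean = np.nanmean(x, axis=1, keepdims=True)
    x = np.where(np.isnan(x), rowmean, x)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if (norms == 0).any():
        # constant profile: zero correlation with everything
        norms = np.where(norms == 0, 1.0, norms)
    c = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    dist = np.clip(1.0 - c, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    order = hierarchy.leaves_list(link)
    index = list(normalized.index)
    return (
        pd.Series(labels, index=index, name="cluster"),
        [index[i] for i in order],
    )


def pca_ordinate(table: PeakAreaTable) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA ordination of samples on their metabolite profiles.

    Rows are mean-imputed, log(1 + area)-transformed and centered; the
    scores come from the eigendecomposition of the sample covariance.
    Returns (scores: sample x PC DataFrame, explained-variance
    fractions, non-increasing).
    """
    if table.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = table.areas.to_numpy(dtype=float)
    rowmean = np.nanmean(x, axis=1, keepdims=True)
    if np.isnan(rowmean).any():
        raise ValueError("pca_ordinate: all-missing metabolite row")
    x = np.where(np.isnan(x), rowmean, x)
    x = np.log1p(x).T  # samples x metabolites
    x = x - x.mean(axis=0, keepdims=True)
    cov = np.cov(x, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise ValueError("pca_ordinate: no variance among samples")
    scores = x @ evecs
    k = min(x.shape)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores[:, :k], index=table.areas.columns, columns=cols),
        evals[:k] / total,
    )


@dataclass
class KilledControlVerdict:
    """Outcome of the active-vs-killed comparison for one metabolite."""

    metabolite_id: str
    detected_in_killed: bool
    p_condition: float = np.nan
    p_interaction: float = np.nan
    evaluable: bool = True
    biologically_controlled: bool = False


def verdict_flag(
    detected_in_killed: bool,
    p_condition: float,
    p_interaction: float,
    alpha: float = 0.05,
) -> bool:
    """Biological-control rule: a metabolite's dynamics are considered
    biologically controlled iff it was never detected in the killed
    controls, or either the condition or the condition x time F-test is
    significant at ``alpha``."""
    if not detected_in_killed:
        return True
    ps = [p for p in (p_condition, p_interaction) if p == p]
    return bool(ps and min(ps) < alpha)


def _detected(sub: PeakAreaTable, metabolite: str) -> bool:
    """A metabolite is 'detected' if >= 50% of replicates are
    non-missing in at least one (stage, time) cell."""
    row = sub.areas.loc[metabolite]
    frac = row.notna().groupby(
        [sub.meta["stage"].to_numpy(), sub.meta["time"].to_numpy()]
    ).mean()
    return bool((frac >= 0.5).any())


def killed_control_test(
    active: PeakAreaTable,
    killed: PeakAreaTable,
    alpha: float = 0.05,
    match_stage: bool = True,
    tukey: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Test which metabolites behave differently in active vs killed crust.

    Per metabolite, an OLS linear model on log(1 + area) with terms
    condition (categorical), time (continuous) and their interaction is
    fit to the combined active + killed observations; F-tests for the
    condition and interaction terms decide significance. A metabolite is
    *biologically controlled* iff it was not detected in the killed
    controls at all, or either p-value is below ``alpha``.

    Killed controls come from a single late successional stage, so by
    default (``match_stage=True``) active samples are restricted to the
    killed samples' stage before fitting.

    Tukey's HSD across condition x time cell means is reported as a
    supplementary table when ``tukey=True``; it does not enter the
    verdict.

    Returns ``(verdicts, tukey_table)`` where verdicts has one row per
    metabolite in the active table.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    killed_stages = set(killed.meta["stage"])
    if match_stage:
        keep = active.meta.index[active.meta["stage"].isin(killed_stages)]
        active_cmp = active.subset_samples(keep)
    else:
        active_cmp = active

    verdicts: list[KilledControlVerdict] = []
    tukey_rows: list[pd.DataFrame] = []
    for m in active.metabolites:
        if m not in killed.areas.index or not _detected(killed, m):
            verdicts.append(
                KilledControlVerdict(m, detected_in_killed=False,
                                     biologically_controlled=True)
            )
            continue
        frames = []
        for tbl, cond in ((active_cmp, "active"), (killed, "killed")):
            y = tbl.areas.loc[m]
            df = pd.DataFrame({
                "y": np.log1p(y.to_numpy(dtype=float)),
                "time": tbl.meta["time"].to_numpy(dtype=float),
                "condition": cond,
            }).dropna(subset=["y"])
            frames.append(df)
        data = pd.concat(frames, ignore_index=True)
        counts = data.groupby("condition").size()
        times = data.groupby("condition")["time"].nunique()
        if len(counts) < 2 or counts.min() < 2 or times.min() < 2:
            verdicts.append(
                KilledControlVerdict(m, detected_in_killed=True, evaluable=False)
            )
            logger.info("killed_control_test: %s unevaluable", m)
            continue
        model = ols("y ~ C(condition) * time", data=data).fit()
        table = sm.stats.anova_lm(model, typ=2)
        p_cond = float(table.loc["C(condition)", "PR(>F)"])
        p_int = float(table.loc["C(condition):time", "PR(>F)"])
        verdicts.append(
            KilledControlVerdict(
                m, True, p_cond, p_int, True,
                verdict_flag(True, p_cond, p_int, alpha),
            )
        )
        if tukey:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            groups = data["condition"] + "@" + data["time"].astype(str)
            if groups.value_counts().min() >= 2 and groups.nunique() >= 2:
                hsd = pairwise_tukeyhsd(data["y"], groups, alpha=alpha)
                t = pd.DataFrame(
                    hsd.summary().data[1:], columns=hsd.summary().data[0]
                )
                t.insert(0, "metabolite_id", m)
                tukey_rows.append(t)

    vdf = pd.DataFrame([vars(v) for v in verdicts]).set_index("metabolite_id")
    tukey_df = pd.concat(tukey_rows, ignore_index=True) if tukey_rows else None
    return vdf, tukey_df


def biologically_controlled(verdicts: pd.DataFrame) -> list[str]:
    """Metabolite ids whose dynamics are under biological control
    (distinguishable from, or absent in, the killed controls)."""
    flag = verdicts["biologically_controlled"].astype(bool)
    excluded = verdicts.index[~flag]
    for m in excluded:
        logger.info("killed-control filter: excluding %s (abiotic control "
                    "cannot be ruled out)", m)
    return list(verdicts.index[flag])
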