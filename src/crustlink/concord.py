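"""Microbe–metabolite concordance statistics.

Spearman rank correlations between taxon relative abundances and
metabolite peak areas across all wetting time points and successional
stages, Benjamini–Hochberg FDR adjustment, the exact two-tailed binomial
test on sign concordance with isolate-based predictions, and the
resulting "foodweb" edge table (solid = concordant, dotted = not, width
= |rho|, star = FDR < 0.05).

Each metabolite observation is a replicate measurement; the taxon
abundance attached to it is the single metagenome estimate for that
sample's (stage, time) group, so taxon values repeat across replicates
(average ranks handle the ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metabolome import PeakAreaTable

logger = logging.getLogger(__name__)

HIGH_RHO = 0.5
STAR_FDR = 0.05


def spearman(x, y) -> tuple[float, float, int]:
    """Spearman rho with a two-sided t-approximation p-value.

    Entries missing in either vector are dropped pairwise; ties get
    average ranks. Requires >= 4 complete pairs. A zero-variance vector
    yields ``(nan, nan, n)``; |rho| = 1 reports p = 0.

    Returns ``(rho, p, n_pairs)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan"), n
    rho, p = stats.spearmanr(x, y)
    if abs(rho) >= 1.0:
        p = 0.0
    return float(rho), float(p), n


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def exact_binom_two_tailed(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-tailed binomial test probability.

    For the symmetric null ``p0 = 0.5`` the doubling rule is used:
    ``p = min(1, 2 * min(P(X <= k), P(X >= k)))`` under Binomial(n, p0).
    For general ``p0`` the minimum-likelihood rule sums the pmf over all
    outcomes no more likely than the observed one. Exact pmf summation
    throughout; no normal approximation.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}], got {k}")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if p0 == 0.5:
        lower = stats.binom.cdf(k, n, p0)
        upper = stats.binom.sf(k - 1, n, p0)
        return float(min(1.0, 2.0 * min(lower, upper)))
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    threshold = pmf[k] * (1 + 1e-7)
    return float(min(1.0, pmf[pmf <= threshold].sum()))


def _abundance_lookup(abundance: pd.DataFrame) -> dict:
    """Map (taxon, stage, time) -> abundance value."""
    lut = {}
    for taxon, row in abundance.iterrows():
        for (stage, time), v in row.items():
            lut[(taxon, stage, float(time))] = float(v)
    return lut


def correlate_pairs(
    peaks: PeakAreaTable,
    abundance: pd.DataFrame,
    taxa=None,
    metabolites=None,
    min_pairs: int = 4,
    rho_threshold: float = HIGH_RHO,
    per_stage: bool = False,
) -> pd.DataFrame:
    """Spearman correlation for every (taxon, metabolite) pair.

    ``abundance`` is a taxon x MultiIndex(stage, time) relative-abundance
    table; each peak-area replicate is paired with its group's abundance.
    By default correlations pool all stages and time points into a
    single rho per pair; ``per_stage=True`` additionally stratifies by
    stage (a "stage" column then distinguishes pooled rows, labeled
    "all", from per-stage rows).

    q-values are BH-adjusted over all evaluable pooled pairs (and
    separately within each stage when stratified). ``highly_correlated``
    flags |rho| >= ``rho_threshold``.
    """
    taxa = list(abundance.index) if taxa is None else list(taxa)
    metabolites = peaks.metabolites if metabolites is None else list(metabolites)
    lut = _abundance_lookup(abundance)
    meta = peaks.meta
    strata = [("all", np.ones(len(meta), dtype=bool))]
    if per_stage:
        strata += [(s, (meta["stage"] == s).to_numpy())
                   for s in sorted(set(meta["stage"]))]

    records = []
    areas = peaks.areas
    for stage_label, mask in strata:
        sel_meta = meta[mask]
        for taxon in taxa:
            x_full = np.array([
                lut.get((taxon, s, float(t)), np.nan)
                for s, t in zip(sel_meta["stage"], sel_meta["time"])
            ])
            for met in metabolites:
                y = areas.loc[met].to_numpy(dtype=float)[mask]
                rec = {
                    "taxon_id": taxon, "metabolite_id": met,
                    "stage": stage_label,
                    "rho": np.nan, "p": np.nan, "q": np.nan,
                    "n_pairs": 0, "evaluable": False,
                    "highly_correlated": False,
                }
                try:
                    rho, p, n = spearman(x_full, y)
                except ValueError:
                    rec["n_pairs"] = int(np.sum(~(np.isnan(x_full) | np.isnan(y))))
                    logger.info("correlate_pairs: %s/%s unevaluable (n=%d)",
                                taxon, met, rec["n_pairs"])
                    records.append(rec)
                    continue
                rec.update(
                    rho=rho, p=p, n_pairs=n,
                    evaluable=not np.isnan(rho),
                    highly_correlated=bool(abs(rho) >= rho_threshold)
                    if not np.isnan(rho) else False,
                )
                records.append(rec)
    df = pd.DataFrame(records)
    df["q"] = np.nan
    for stage_label in df["stage"].unique():
        m = (df["stage"] == stage_label) & df["evaluable"]
        if m.any():
            df.loc[m, "q"] = bh_fdr(df.loc[m, "p"].to_numpy())
    return df


@dataclass
class ConcordanceSummary:
    """Directionality score of predictions against observed correlations."""

    n_evaluated: int
    n_concordant: int
    proportion: float
    p_binomial: float
    per_class: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "n_concordant": self.n_concordant,
            "proportion": self.proportion,
            "p_binomial": self.p_binomial,
            "per_class": self.per_class.to_dict(orient="records"),
        }


def evaluate_concordance(
    correlations: pd.DataFrame, predictions: pd.DataFrame
) -> tuple[ConcordanceSummary, pd.DataFrame]:
    """Score sign concordance of observed correlations with predictions.

    For each predicted (taxon, metabolite) relationship the observed
    sign is ``sign(rho)`` from the pooled correlation; a pair whose
    correlation is missing, unevaluable, or exactly zero carries no
    directional information and is excluded from the trial count
    (logged). The binomial p-value is the exact two-tailed test of the
    concordant count against chance (p0 = 0.5), and per-class
    (consumed / released) breakdowns are reported alongside.
    """
    if predictions.empty:
        raise ValueError("empty prediction set")
    pooled = correlations[correlations["stage"] == "all"] \
        if "stage" in correlations.columns else correlations
    merged = predictions.merge(
        pooled, on=["taxon_id", "metabolite_id"], how="left",
        suffixes=("_pred", ""),
    )
    rows = []
    for rec in merged.itertuples(index=False):
        rho = rec.rho
        evaluable = (
            getattr(rec, "evaluable", True) is True
            and rho == rho  # not NaN
            and rho != 0.0
        )
        observed = int(np.sign(rho)) if evaluable else 0
        if not evaluable:
            logger.info("evaluate_concordance: %s/%s excluded (no usable rho)",
                        rec.taxon_id, rec.metabolite_id)
        rows.append({
            "taxon_id": rec.taxon_id,
            "metabolite_id": rec.metabolite_id,
            "predicted": rec.predicted,
            "expected_sign": rec.expected_sign,
            "rho": rho,
            "p": getattr(rec, "p", np.nan),
            "q": getattr(rec, "q", np.nan),
            "observed_sign": observed,
            "evaluable": evaluable,
            "concordant": bool(evaluable and observed == rec.expected_sign),
        })
    records = pd.DataFrame(rows)
    ev = records[records["evaluable"]]
    n_eval = int(len(ev))
    n_conc = int(ev["concordant"].sum())
    if n_eval == 0:
        raise ValueError("no evaluable prediction has a usable correlation")
    per_class = (
        ev.groupby("predicted")
        .agg(n_evaluated=("concordant", "size"),
             n_concordant=("concordant", "sum"))
        .reset_index()
    )
    per_class["proportion"] = per_class["n_concordant"] / per_class["n_evaluated"]
    summary = ConcordanceSummary(
        n_evaluated=n_eval,
        n_concordant=n_conc,
        proportion=n_conc / n_eval,
        p_binomial=exact_binom_two_tailed(n_conc, n_eval, 0.5),
        per_class=per_class,
    )
    return summary, records


def build_foodweb(records: pd.DataFrame) -> pd.DataFrame:
    """Edge table for the microbe–metabolite foodweb figure.

    One edge per evaluated prediction: ``style`` solid (concordant) or
    dotted, ``weight`` = |rho|, ``starred`` iff q < 0.05.
    """
    edges = records.copy()
    edges["style"] = np.where(edges["concordant"], "solid", "dotted")
    edges["weight"] = edges["rho"].abs()
    edges["starred"] = edges["q"] < STAR_FDR
    cols = ["taxon_id", "metabolite_id", "predicted", "observed_sign",
            "concordant", "style", "weight", "starred", "rho", "p", "q"]
    return edges[cols]


def foodweb_graph(edges: pd.DataFrame):
    """Bipartite taxon–metabolite graph (networkx) for export, nodes
    typed "taxon" / "metabolite" with edge attributes from the table."""
    import networkx as nx

    g = nx.Graph()
    for rec in edges.itertuples(index=False):
        g.add_node(rec.taxon_id, kind="taxon")
        g.add_node(rec.metabolite_id, kind="metabolite")
        g.add_edge(
            rec.taxon_id, rec.metabolite_id,
            predicted=rec.predicted,
            concordant=bool(rec.concordant),
            style=rec.style,
            weight=0.0 if pd.isna(rec.weight) else float(rec.weight),
            starred=bool(rec.starred),
        )
    return g
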