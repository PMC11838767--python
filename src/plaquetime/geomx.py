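"""Single-plaque spatial-transcriptomics chain.

Probe-level QC (low-count floor + Grubbs outlier screening within
multi-probe targets), collapse to gene level by geometric mean, quantile
normalisation across ROIs, per-gene Pearson correlation against the
MSI-derived plaque-age coordinate with Benjamini-Hochberg correction, and
hypergeometric over-representation analysis of the resulting positive /
negative gene lists against GMT gene sets, with all surviving genes as the
background universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Probe-QC knobs following platform convention (the vendor defaults are
    not published; every parameter is surfaced here)."""

    low_count_floor: float = 10.0  # geometric-mean counts below this -> probe out
    grubbs_alpha: float = 0.05
    grubbs_max_outlier_fraction: float = 0.2  # flagged in > this fraction of ROIs
    pseudocount: float = 1.0
    roi_drop_list: tuple[str, ...] = ()  # manual morphology exclusions


def grubbs_statistic(
    values: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, int | None]:
    """Two-sided Grubbs test for a single outlier.

    Returns (G, critical value, index of the outlier or None). G is
    max |x - mean| / sd; the critical value comes from the t distribution at
    significance ``alpha`` (two-sided, Bonferroni over the n candidates).
    Zero-variance input is degenerate: no outlier.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    sd = x.std(ddof=1)
    if sd == 0.0:
        return 0.0, np.inf, None
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    g_crit = float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))
    return g, g_crit, (idx if g > g_crit else None)


def probe_qc(
    counts: pd.DataFrame, targets: pd.Series, config: QCConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a probe x ROI count table.

    ``counts`` is indexed by probe id; ``targets`` maps probe id -> gene.
    Probes fall to (a) a geometric-mean low-count floor, or (b) a Grubbs
    outlier screen run per ROI on log-scale probe values within each
    multi-probe target (single- and double-probe targets are never Grubbs
    tested), removing probes flagged in more than
    ``grubbs_max_outlier_fraction`` of ROIs. Returns the filtered table and
    an exclusion log (probe, target, reason).
    """
    config = config or QCConfig()
    counts = counts.drop(columns=list(config.roi_drop_list), errors="ignore")
    if counts.columns.duplicated().any():
        raise ValueError("ROI column ids must be unique")
    excluded: list[dict] = []

    pc = config.pseudocount
    gm = np.exp(np.log(counts + pc).mean(axis=1)) - pc
    low = gm < config.low_count_floor
    for probe in counts.index[low]:
        excluded.append(
            {"probe": probe, "target": targets[probe],
             "reason": f"geometric mean {gm[probe]:.2f} below floor"}
        )
    kept = counts.loc[~low]

    grubbs_out: list[str] = []
    for target, probes in targets.loc[kept.index].groupby(targets):
        ids = probes.index.tolist()
        if len(ids) < 3:
            continue  # Grubbs needs n >= 3
        sub = np.log(kept.loc[ids] + pc)
        flagged = pd.Series(0, index=ids)
        for roi in sub.columns:
            _, _, out = grubbs_statistic(sub[roi].to_numpy(), config.grubbs_alpha)
            if out is not None:
                flagged.iloc[out] += 1
        frac = flagged / sub.shape[1]
        for probe in frac.index[frac > config.grubbs_max_outlier_fraction]:
            grubbs_out.append(probe)
            excluded.append(
                {"probe": probe, "target": target,
                 "reason": f"Grubbs outlier in {frac[probe]:.0%} of ROIs"}
            )
    kept = kept.drop(index=grubbs_out)

    lost = set(targets.unique()) - set(targets.loc[kept.index].unique())
    for t in sorted(lost):
        log.warning("target %s lost all probes during QC", t)
    return kept, pd.DataFrame(excluded, columns=["probe", "target", "reason"])


def collapse_targets(
    counts: pd.DataFrame, targets: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Gene x ROI table: geometric mean over each target's surviving probes.

    The geometric mean is taken on counts + ``pseudocount`` (then the
    pseudocount is subtracted back), so all-zero probes yield zero.
    """
    logc = np.log(counts + pseudocount)
    gene = np.exp(logc.groupby(targets.loc[counts.index]).mean()) - pseudocount
    gene.index.name = "gene"
    return gene.clip(lower=0.0)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classic rank-mean quantile normalisation across columns (ROIs).

    Each column's values are replaced by the across-column mean of the
    order statistics at their rank; ties receive the average of the
    reference values at their tied ranks. Idempotent; afterwards tie-free
    columns share exactly the same value multiset.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    arr = matrix.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    n = arr.shape[0]
    out = np.empty_like(arr)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, ref)
    res = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    res.attrs["normalization"] = "quantile"
    return res


def correlate_genes(
    matrix: pd.DataFrame,
    age: pd.Series | np.ndarray,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Pearson correlation with the plaque-age coordinate.

    Returns a table with columns ``r, p, q, direction`` indexed by gene.
    q is Benjamini-Hochberg across all testable genes; ``direction`` is
    "positive"/"negative" for genes with p below ``p_threshold`` (the
    selection feeding ORA), "ns" otherwise. Constant genes are excluded
    and logged.
    """
    if isinstance(age, pd.Series):
        age = age.reindex(matrix.columns).to_numpy(dtype=float)
    else:
        age = np.asarray(age, dtype=float)
    if len(age) != matrix.shape[1]:
        raise ValueError("age vector must align with ROI columns")
    n = len(age)
    if n < 4:
        raise ValueError("need at least 4 ROIs for correlation")
    x = matrix.to_numpy(dtype=float)
    keep = x.std(axis=1) > 0
    for g in matrix.index[~keep]:
        log.info("gene %s excluded from correlation: constant expression", g)
    x = x[keep]
    genes = matrix.index[keep]
    xm = x - x.mean(axis=1, keepdims=True)
    ym = age - age.mean()
    denom = np.sqrt((xm**2).sum(axis=1) * (ym**2).sum())
    r = (xm @ ym) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    direction = np.where(
        p < p_threshold, np.where(r > 0, "positive", "negative"), "ns"
    )
    return pd.DataFrame(
        {"r": r, "p": p, "q": q, "direction": direction}, index=genes
    )


@dataclass
class ORAResult:
    table: pd.DataFrame  # set, slice, overlap, set_size, n_selected, universe, p, q, passed
    selection_size: int
    universe_size: int


def ora(
    selected: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    slices: dict[str, str] | None = None,
    p_cutoff: float = 0.05,
    q_cutoff: float = 0.05,
) -> ORAResult:
    """Hypergeometric over-representation of ``selected`` genes in each set.

    Sets are intersected with the universe (all genes surviving QC). The
    upper-tail p is P(X >= overlap) drawing ``len(selected)`` genes without
    replacement; BH q is computed within each ontology slice (``slices``
    maps set name -> slice label, default one slice). A set passes at
    p <= 0.05 and q <= 0.05. An empty selection gives p = 1 everywhere.
    """
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    m = len(universe)
    n_sel = len(selected)
    slices = slices or {name: "all" for name in gene_sets}
    rows = []
    for name, genes in gene_sets.items():
        in_universe = genes & universe
        k = len(in_universe)
        overlap = len(in_universe & selected)
        if n_sel == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, m, k, n_sel))
        rows.append(
            {"set": name, "slice": slices.get(name, "all"), "overlap": overlap,
             "set_size": k, "n_selected": n_sel, "universe": m, "p": p}
        )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for _, idx in table.groupby("slice").groups.items():
        _, q, _, _ = multipletests(table.loc[idx, "p"].to_numpy(), method="fdr_bh")
        table.loc[idx, "q"] = q
    table["passed"] = (table["p"] <= p_cutoff) & (table["q"] <= q_cutoff)
    return ORAResult(table, n_sel, m)
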