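"""Cross-classification enrichment tables and t-statistic profiles.

Two classifications of the same items are cross-tabulated and every
cell tested with cumulative hypergeometric tests (upper tail for
enrichment, lower tail for deprivation). Numeric per-item values
(e.g. log2 fold changes) are profiled by cluster with Welch two-sample
t-tests against the complement. An iterative column-wise sorting
procedure arranges table rows for display, and a rendering contract
turns any of these tables into a plotting-toolkit-agnostic style sheet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Classification


def hypergeom_tests(x: int, n_draw: int, k_succ: int, universe: int) -> tuple[float, float]:
    """Cumulative hypergeometric enrichment/deprivation p-values.

    With X ~ Hypergeometric(universe, k_succ, n_draw):
    p_enrich = P(X >= x), p_deplete = P(X <= x).
    """
    if x > min(n_draw, k_succ):
        raise ValueError(
            f"overlap {x} exceeds min(draws={n_draw}, successes={k_succ})"
        )
    if x < 0:
        raise ValueError("overlap must be non-negative")
    p_enrich = float(stats.hypergeom.sf(x - 1, universe, k_succ, n_draw))
    p_deplete = float(stats.hypergeom.cdf(x, universe, k_succ, n_draw))
    return min(p_enrich, 1.0), min(p_deplete, 1.0)


@dataclass
class OverlapTable:
    """Cross-tabulation of two classifications with per-cell tests."""

    counts: pd.DataFrame  # row classes x column classes
    p_enrich: pd.DataFrame
    p_deplete: pd.DataFrame
    universe: int
    row_order: list = field(default_factory=list)
    cut_row: int | None = None  # rows below this index are "below the red line"
    p_enrich_bh: pd.DataFrame | None = None  # FDR-adjusted, for convenience only

    def __post_init__(self):
        if not self.row_order:
            self.row_order = list(self.counts.index)

    @property
    def row_margins(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return self.counts.sum(axis=0)


def cross_tabulate(class_a: Classification, class_b: Classification) -> OverlapTable:
    """Cross-tabulate shared items and test every cell.

    Restricted to items present in both classifications; the universe
    for the hypergeometric tests is the shared item count.
    """
    shared = sorted(set(class_a.labels) & set(class_b.labels))
    if not shared:
        raise ValueError("no shared items between the two classifications")
    a = pd.Series({i: class_a.labels[i] for i in shared})
    b = pd.Series({i: class_b.labels[i] for i in shared})
    counts = pd.crosstab(a, b)
    counts = counts.reindex(index=sorted(counts.index), columns=sorted(counts.columns))
    n = len(shared)
    p_en = counts.astype(float).copy()
    p_de = counts.astype(float).copy()
    for r in counts.index:
        for c in counts.columns:
            pe, pdp = hypergeom_tests(
                int(counts.at[r, c]),
                int(counts.loc[r].sum()),
                int(counts[c].sum()),
                n,
            )
            p_en.at[r, c], p_de.at[r, c] = pe, pdp
    bh = p_en.copy()
    bh.values.flat = multipletests(p_en.values.ravel(), method="fdr_bh")[1]
    return OverlapTable(counts, p_en, p_de, universe=n, p_enrich_bh=bh)


@dataclass
class TProfile:
    """Welch t statistics of in-cluster values vs all other values."""

    t: pd.DataFrame  # cluster x contrast
    p: pd.DataFrame
    n_in: pd.Series
    n_total: int


def t_profile(values: pd.DataFrame, classification: Classification) -> TProfile:
    """Per cluster and contrast: Welch two-sided t of cluster vs complement.

    ``values`` is an item x contrast table. Positive t means the
    cluster's values exceed the rest (upregulation for fold changes).
    """
    shared = [i for i in values.index if i in classification.labels]
    if not shared:
        raise ValueError("no classified items in the values table")
    sub = values.loc[shared]
    groups = pd.Series({i: classification.labels[i] for i in shared})
    clusters = sorted(groups.unique())
    t = pd.DataFrame(index=clusters, columns=values.columns, dtype=float)
    p = pd.DataFrame(index=clusters, columns=values.columns, dtype=float)
    n_in = pd.Series(0, index=clusters, dtype=int)
    for cl in clusters:
        mask = (groups == cl).values
        n_in[cl] = int(mask.sum())
        for col in values.columns:
            res = stats.ttest_ind(
                sub[col].values[mask], sub[col].values[~mask], equal_var=False
            )
            t.at[cl, col] = res.statistic
            p.at[cl, col] = res.pvalue
    return TProfile(t, p, n_in, len(shared))


def sort_overlaps(
    table: OverlapTable,
    p_sort: float,
    column_order=None,
    drop_remainder: bool = False,
) -> OverlapTable:
    """Iterative column-wise row sorting of an enrichment table.

    Walking the columns in order, rows enriched at p_enrich <= p_sort
    in the current column (and not yet placed) are appended, sorted by
    increasing p-value. Rows never placed end up below the cut ("red
    line") in their original order, or are dropped.
    """
    cols = list(column_order) if column_order is not None else list(table.counts.columns)
    remaining = list(table.counts.index)
    placed: list = []
    for col in cols:
        hits = [(float(table.p_enrich.at[r, col]), i) for i, r in enumerate(remaining)
                if table.p_enrich.at[r, col] <= p_sort]
        hits.sort(key=lambda t: (t[0], t[1]))
        chosen = [remaining[i] for _, i in hits]
        placed.extend(chosen)
        remaining = [r for r in remaining if r not in chosen]
    cut = len(placed)
    row_order = placed if drop_remainder else placed + remaining
    return OverlapTable(
        table.counts,
        table.p_enrich,
        table.p_deplete,
        table.universe,
        row_order=row_order,
        cut_row=cut,
        p_enrich_bh=table.p_enrich_bh,
    )


def render_profile(obj, p_min: float = 1e-10, p_txt: float = 1e-5) -> pd.DataFrame:
    """Style-sheet contract for table plots.

    Per cell: displayed text (overlap count, or rounded t), background
    intensity = min(1, log2(p)/log2(p_min)) so p=1 is white and
    p <= p_min is full color, hue (black for categorical enrichment,
    red for t < 0, blue for t > 0) and text color (white iff p <= p_txt).
    Returned as a long-format frame any plotting layer can consume.
    """
    if not 0 < p_min < 1:
        raise ValueError("p_min must be in (0, 1)")
    rows = []
    if isinstance(obj, OverlapTable):
        order = obj.row_order
        for r in order:
            for c in obj.counts.columns:
                p = float(obj.p_enrich.at[r, c])
                rows.append(
                    {
                        "row": r,
                        "col": c,
                        "text": str(int(obj.counts.at[r, c])),
                        "intensity": _intensity(p, p_min),
                        "hue": "black",
                        "text_color": "white" if p <= p_txt else "black",
                        "p": p,
                    }
                )
    elif isinstance(obj, TProfile):
        for r in obj.t.index:
            for c in obj.t.columns:
                tval, p = float(obj.t.at[r, c]), float(obj.p.at[r, c])
                rows.append(
                    {
                        "row": r,
                        "col": c,
                        "text": str(int(round(tval))),
                        "intensity": _intensity(p, p_min),
                        "hue": "red" if tval < 0 else "blue",
                        "text_color": "white" if p <= p_txt else "black",
                        "p": p,
                    }
                )
    else:
        raise TypeError(f"cannot render {type(obj).__name__}")
    return pd.DataFrame(rows)


def _intensity(p: float, p_min: float) -> float:
    if p <= 0:
        return 1.0
    return float(min(1.0, np.log2(p) / np.log2(p_min)))
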