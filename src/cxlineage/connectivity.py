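"""Synaptic summaries over connector tables.

All statistics are descriptive counts in the connectomics sense:
"connection strength" is the total synapse count between an ordered
neuron pair, matrices are source-group x target-group synapse sums, and
"lateral input" fractions count synapses outside the central-complex
compartments.  Groupings are plain mappings neuron_id -> group label;
neurons missing from a grouping fall into ``"other"``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "build_connection_matrix",
    "normalize_to_max",
    "input_fraction_by_group",
    "tbar_counts",
    "pairwise_strength_ecdf",
    "source_exclusivity",
    "synapse_weight_by_upstream",
    "upstream_totals",
]

OTHER = "other"


def _group(series: pd.Series, grouping) -> pd.Series:
    return series.map(lambda n: grouping.get(n, OTHER))


def build_connection_matrix(connectors: pd.DataFrame, src_grouping, tgt_grouping,
                            region: str | None = None,
                            regions=None) -> pd.DataFrame:
    """Source-group x target-group summed synapse counts.

    ``region`` (single name) or ``regions`` (iterable) restrict rows by
    compartment.  The grand total equals the filtered connector weight
    sum (conservation); labels present in the groupings are preserved
    even when a row/column is empty.
    """
    df = connectors
    if region is not None:
        df = df[df["compartment"] == region]
    if regions is not None:
        df = df[df["compartment"].isin(set(regions))]
    src = _group(df["pre_neuron"], src_grouping)
    tgt = _group(df["post_neuron"], tgt_grouping)
    mat = (pd.DataFrame({"s": src, "t": tgt, "w": df["weight"].to_numpy()})
           .pivot_table(index="s", columns="t", values="w", aggfunc="sum", fill_value=0))
    src_labels = sorted(set(src_grouping.values()) | set(mat.index))
    tgt_labels = sorted(set(tgt_grouping.values()) | set(mat.columns))
    mat = mat.reindex(index=src_labels, columns=tgt_labels, fill_value=0).astype(np.int64)
    mat.index.name, mat.columns.name = "source", "target"
    return mat


def normalize_to_max(m: pd.DataFrame) -> pd.DataFrame:
    """Divide every entry by the global maximum (strongest connection = 1).

    An all-zero matrix is returned as zeros with a warning.
    """
    mx = m.to_numpy().max() if m.size else 0
    if mx <= 0:
        warnings.warn("normalize_to_max: matrix has no positive entry")
        return m.astype(float)
    return m.astype(float) / float(mx)


def input_fraction_by_group(connectors: pd.DataFrame, tgt_grouping,
                            exclude_regions=(), count_side: str = "post"
                            ) -> pd.Series:
    """Fraction of input synapses landing on each target group.

    Counts connector weight onto neurons covered by ``tgt_grouping``
    (postsynaptic side by default), excluding rows in
    ``exclude_regions`` — pass the CX compartment names to count lateral
    inputs only.  Fractions sum to 1 when the total is positive; an
    empty total yields an all-NA series with a warning.
    """
    col = "post_neuron" if count_side == "post" else "pre_neuron"
    df = connectors[~connectors["compartment"].isin(set(exclude_regions))]
    df = df[df[col].isin(set(tgt_grouping))]
    groups = sorted(set(tgt_grouping.values()))
    if df.empty or df["weight"].sum() == 0:
        warnings.warn("input_fraction_by_group: no synapses after exclusion")
        return pd.Series([np.nan] * len(groups), index=groups, name="fraction")
    g = _group(df[col], tgt_grouping)
    counts = df.groupby(g.to_numpy())["weight"].sum().reindex(groups, fill_value=0)
    frac = counts / counts.sum()
    frac.name = "fraction"
    return frac


def tbar_counts(connectors: pd.DataFrame, neuron_set, region: str) -> pd.Series:
    """T-bars formed by each neuron of ``neuron_set`` in ``region``
    (presynaptic, kind TBAR only; absent neurons count 0)."""
    df = connectors[(connectors["kind"] == "TBAR")
                    & (connectors["compartment"] == region)
                    & connectors["pre_neuron"].isin(set(neuron_set))]
    counts = df.groupby("pre_neuron")["weight"].sum()
    return counts.reindex(list(neuron_set), fill_value=0).astype(np.int64)


def pairwise_strength_ecdf(connectors: pd.DataFrame, src_set, region: str
                           ) -> pd.DataFrame:
    """ECDF of per-(pre, post)-pair connection strengths within a region.

    Returns a frame (strength, F) with F right-continuous,
    F(x) = #{strengths <= x} / N; empty when no pair exists (warned).
    """
    df = connectors[(connectors["compartment"] == region)
                    & connectors["pre_neuron"].isin(set(src_set))]
    strengths = df.groupby(["pre_neuron", "post_neuron"])["weight"].sum().to_numpy()
    if len(strengths) == 0:
        warnings.warn("pairwise_strength_ecdf: no connection pairs")
        return pd.DataFrame(columns=["strength", "F"])
    xs = np.sort(np.unique(strengths))
    F = np.searchsorted(np.sort(strengths), xs, side="right") / len(strengths)
    return pd.DataFrame({"strength": xs, "F": F})


def source_exclusivity(m: pd.DataFrame, partition) -> pd.Series:
    """Per-target fraction of synapses from its dominant source super-group.

    ``partition`` maps each source group label to one of two super-group
    labels; exclusivity holds for a target exactly when its fraction is
    1.0.  Zero columns yield NA.
    """
    supers = sorted(set(partition.values()))
    if len(supers) != 2:
        raise ValueError("partition must define exactly 2 super-groups")
    sup = pd.Series({g: partition[g] for g in m.index if g in partition})
    missing = [g for g in m.index if g not in partition and m.loc[g].sum() > 0]
    if missing:
        raise ValueError(f"source groups not covered by partition: {missing}")
    collapsed = m.loc[sup.index].groupby(sup).sum().reindex(supers, fill_value=0)
    total = collapsed.sum(axis=0)
    frac = collapsed.max(axis=0) / total.where(total > 0)
    frac.name = "dominant_fraction"
    return frac


def upstream_totals(connectors: pd.DataFrame, src_set, region: str | None = None
                    ) -> pd.Series:
    """Summed synapse weight from ``src_set`` onto each postsynaptic neuron."""
    df = connectors[connectors["pre_neuron"].isin(set(src_set))]
    if region is not None:
        df = df[df["compartment"] == region]
    return df.groupby("post_neuron")["weight"].sum()


def synapse_weight_by_upstream(out_synapses: pd.DataFrame,
                               totals: pd.Series) -> pd.DataFrame:
    """Shade each output synapse by its neuron's relative upstream drive.

    The weight of a synapse made by neuron n is n's total upstream input
    divided by the maximum such total over all recorded targets, so
    weights lie in [0, 1] and the most strongly driven neuron's synapses
    weigh 1.  Neurons with no upstream record get 0 and are flagged.
    """
    out = out_synapses.copy()
    mx = float(totals.max()) if len(totals) else 0.0
    if mx <= 0:
        out["shade_weight"] = 0.0
        out["no_upstream"] = True
        return out
    t = out["pre_neuron"].map(totals)
    out["no_upstream"] = t.isna()
    out["shade_weight"] = (t.fillna(0.0) / mx).astype(float)
    return out
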