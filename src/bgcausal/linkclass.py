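"""Classification of discovered links by timing, nature and persistence.

Timing follows directly from the lag: instantaneous (lag 0, unoriented),
single-delayed (lag 1, one repetition time) or double-delayed (lag 2).

Nature encodes which statistic detects the link, by precedence:

* **linear** -- significant under partial correlation (PC), regardless of the
  other methods (PC is the most sensitive test for linear dependence);
* **non-linear** -- significant under GPDC but not PC;
* **complex** -- significant only under CMIknn (dependence invisible to both
  correlation and regression residuals, e.g. multiplicative noise).

Persistence compares the two experimental conditions: a link significant (by
any method) in both is **permanent**; otherwise it is tagged with the single
condition in which it appears (e.g. ``resting-only``).

``normalize_statistics`` reproduces the reporting convention of dividing every
statistic by the per-method, per-condition maximum absolute statistic, so the
strongest link of each method maps to +/-1 and magnitudes are comparable
across methods.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .pcmci import CausalGraph

TIMING = {0: "instantaneous", 1: "single-delayed", 2: "double-delayed"}
NATURES = ("linear", "non-linear", "complex")

__all__ = [
    "ClassifiedLink",
    "classify_nature",
    "classify_persistence",
    "normalize_statistics",
    "tabulate_counts",
    "long_table",
    "wide_matrix",
]


@dataclass
class ClassifiedLink:
    """One link with its full taxonomy and per-condition/method evidence."""

    source: str
    target: str
    lag: int
    timing: str
    nature: str
    persistence: str
    methods: tuple[str, ...]  # supporting methods (union over conditions)
    evidence: dict = field(default_factory=dict)  # (condition, method) -> (stat, p)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.source, self.target, self.lag)


def _canonical_key(source: str, target: str, lag: int) -> tuple[str, str, int]:
    if lag == 0 and target < source:
        return (target, source, 0)
    return (source, target, lag)


def _nature_from_methods(methods) -> str:
    if "PC" in methods:
        return "linear"
    if "GPDC" in methods:
        return "non-linear"
    return "complex"


def classify_nature(graphs: dict[str, CausalGraph]) -> dict[tuple[str, str, int], dict]:
    """Merge the per-method graphs of one condition into nature-labelled links.

    Returns ``{(source, target, lag): {"nature", "methods", "evidence"}}``.
    All graphs must come from the same condition (same series and config up to
    the CI method).
    """
    conditions = {g.condition for g in graphs.values()}
    if len(conditions) > 1:
        raise ValueError(f"graphs of different conditions passed: {conditions}")
    merged: dict[tuple[str, str, int], dict] = {}
    for method, graph in graphs.items():
        for link in graph.links:
            key = _canonical_key(link.source, link.target, link.lag)
            rec = merged.setdefault(key, {"methods": set(), "evidence": {}})
            rec["methods"].add(method)
            rec["evidence"][(graph.condition, method)] = (link.statistic, link.p_value)
    for rec in merged.values():
        rec["nature"] = _nature_from_methods(rec["methods"])
    return merged


def classify_persistence(
    by_condition: dict[str, dict[tuple[str, str, int], dict]]
) -> list[ClassifiedLink]:
    """Combine the nature-classified links of both conditions.

    Nature of a permanent link is assigned from the union of supporting
    methods across conditions (same precedence rules).
    """
    conditions = sorted(by_condition)
    all_keys = sorted(set().union(*(set(d) for d in by_condition.values())))
    out: list[ClassifiedLink] = []
    for key in all_keys:
        present = [c for c in conditions if key in by_condition[c]]
        if len(present) == len(conditions) and len(conditions) > 1:
            persistence = "permanent"
        else:
            persistence = f"{present[0]}-only"
        methods: set[str] = set()
        evidence: dict = {}
        for c in present:
            rec = by_condition[c][key]
            methods |= set(rec["methods"])
            evidence.update(rec["evidence"])
        src, tgt, lag = key
        out.append(
            ClassifiedLink(
                source=src, target=tgt, lag=lag,
                timing=TIMING.get(lag, f"lag-{lag}"),
                nature=_nature_from_methods(methods),
                persistence=persistence,
                methods=tuple(sorted(methods)),
                evidence=evidence,
            )
        )
    return out


def normalize_statistics(table: pd.DataFrame) -> pd.DataFrame:
    """Scale statistics to the per-method, per-condition maximum magnitude.

    Expects a long table with at least ``method``, ``condition`` and
    ``statistic`` columns; adds a ``normalized`` column. Signs are preserved,
    the strongest entry of each group maps to +/-1, and the ordering of
    magnitudes within each group is unchanged.
    """
    table = table.copy()
    if table.empty:
        table["normalized"] = pd.Series(dtype=float)
        return table

    def _scale(group: pd.Series) -> pd.Series:
        m = group.abs().max()
        if m == 0:
            warnings.warn("all statistics of one method/condition are zero")
            return group * 0.0
        return group / m

    table["normalized"] = table.groupby(["method", "condition"], group_keys=False)[
        "statistic"
    ].apply(_scale)
    return table


def long_table(classified: list[ClassifiedLink]) -> pd.DataFrame:
    """One row per link x condition x method, with taxonomy columns."""
    rows = []
    for cl in classified:
        for (condition, method), (stat, p) in sorted(cl.evidence.items()):
            rows.append(
                {"source": cl.source, "target": cl.target, "lag": cl.lag,
                 "timing": cl.timing, "nature": cl.nature,
                 "persistence": cl.persistence, "condition": condition,
                 "method": method, "statistic": stat, "p": p}
            )
    return pd.DataFrame(
        rows,
        columns=["source", "target", "lag", "timing", "nature", "persistence",
                 "condition", "method", "statistic", "p"],
    )


def wide_matrix(
    table: pd.DataFrame, method: str, condition: str, lag: int,
    value: str = "normalized",
) -> pd.DataFrame:
    """Response x causative matrix of one method/condition/lag (report style)."""
    sub = table[(table["method"] == method) & (table["condition"] == condition)
                & (table["lag"] == lag)]
    return sub.pivot_table(index="target", columns="source", values=value)


def tabulate_counts(classified: list[ClassifiedLink]) -> pd.DataFrame:
    """Exhaustive, mutually exclusive counts by timing x nature x persistence."""
    timings = list(dict.fromkeys(TIMING.values()))
    persistences = sorted({cl.persistence for cl in classified})
    rows = []
    for timing in timings:
        for nature in NATURES:
            for persistence in persistences or ["permanent"]:
                n = sum(
                    1 for cl in classified
                    if cl.timing == timing and cl.nature == nature
                    and cl.persistence == persistence
                )
                rows.append({"timing": timing, "nature": nature,
                             "persistence": persistence, "count": n})
    df = pd.DataFrame(rows, columns=["timing", "nature", "persistence", "count"])
    assert df["count"].sum() == len(classified)
    return df


def screen_by_detection_frequency(
    classified: list[ClassifiedLink],
    alpha: float = 0.01,
    n_methods: int = 3,
    n_conditions: int = 2,
    level: float = 0.05,
) -> list[ClassifiedLink]:
    """Optional screen: keep links detected more often than chance.

    Each link has ``n_methods x n_conditions`` detection opportunities; under
    a global null every one succeeds independently with probability ``alpha``.
    A link survives if its detection count is improbably high under that
    binomial null (one-sided p < ``level``). Off by default in the pipeline:
    the significance-based rules already define the taxonomy, this screen
    additionally suppresses links carried by a single marginal detection.
    """
    from scipy.stats import binom

    n_trials = n_methods * n_conditions
    out = []
    for cl in classified:
        k = len(cl.evidence)
        p = float(binom.sf(k - 1, n_trials, alpha))
        if p < level:
            out.append(cl)
    return out


def plot_graph(classified: list[ClassifiedLink], path=None, ax=None):
    """Node-link diagram of the classified graph (optional; needs matplotlib).

    Edge colour encodes nature, style encodes persistence; lag-0 edges are
    drawn without arrowheads.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import networkx as nx

    g = nx.MultiDiGraph()
    for cl in classified:
        g.add_edge(cl.source, cl.target, **cl.__dict__)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    pos = nx.circular_layout(g)
    colors = {"linear": "tab:green", "non-linear": "tab:purple", "complex": "tab:cyan"}
    styles = {"permanent": "solid"}
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color="lightgray", node_size=1200)
    nx.draw_networkx_labels(g, pos, ax=ax)
    for u, v, d in g.edges(data=True):
        ax.annotate(
            "", xy=pos[v], xytext=pos[u],
            arrowprops=dict(
                arrowstyle="-|>" if d["lag"] > 0 else "-",
                color=colors.get(d["nature"], "k"),
                linestyle=styles.get(d["persistence"], "dashed"),
                shrinkA=18, shrinkB=18,
            ),
        )
    ax.set_axis_off()
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
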