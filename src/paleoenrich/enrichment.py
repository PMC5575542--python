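"""Substitution-enrichment tests over phylogenetic windows.

A phylogenetic window is the path between two named ancestors (start
ancestral to end).  For each window the maximum-likelihood ancestral
sequences at its two endpoints are compared site by site and classified into
the 2x2 table

    a: substituted and in region      b: unsubstituted and in region
    c: substituted and out of region  d: unsubstituted and out of region

Sites where either endpoint carries a gap are excluded by default (indel
history is reconstructed separately by parsimony).  Enrichment of a region is
tested with Fisher's exact test; a (region, window) cell is flagged
significant when its odds ratio exceeds 1.5 and its p-value is below .05
(both strict).  A Benjamini-Hochberg column is reported alongside but does
not enter the significance rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .alphabet import GAP
from .regions import RegionMap
from .trees import mrca_node, name_internal_nodes

__all__ = [
    "ContingencyTable",
    "PhylogeneticWindow",
    "count_substitutions",
    "fisher_exact",
    "odds_ratio",
    "define_windows",
    "enrichment_scan",
    "WindowError",
]

OR_THRESHOLD = 1.5
P_THRESHOLD = 0.05
#: relative slack when comparing point probabilities in the two-sided tail
_TWO_SIDED_SLACK = 1.0 + 1e-7


class WindowError(ValueError):
    """Requested ancestors do not lie on one root-to-tip path."""


@dataclass(frozen=True)
class ContingencyTable:
    """Four-category site counts for one (region, window) cell."""

    a: int  # substituted, in region
    b: int  # unsubstituted, in region
    c: int  # substituted, out of region
    d: int  # unsubstituted, out of region
    excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d, self.excluded) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class PhylogeneticWindow:
    """A branch path between two named ancestors (start is ancestral)."""

    name: str
    start: str
    end: str

    def __post_init__(self) -> None:
        if self.start == self.end:
            raise WindowError("window endpoints must differ")


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_substitutions(
    seq_start: str,
    seq_end: str,
    region_columns: Iterable[int],
    gap_policy: str = "exclude",
) -> ContingencyTable:
    """Classify alignment sites by substitution status and region membership.

    ``gap_policy='exclude'`` drops sites where either endpoint has a gap;
    ``'count-as-substitution'`` treats residue<->gap changes as substitutions
    (sites gapped at both ends are always excluded).
    """
    if len(seq_start) != len(seq_end):
        raise ValueError("endpoint sequences must have equal (aligned) length")
    if gap_policy not in ("exclude", "count-as-substitution"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    s = np.frombuffer(seq_start.upper().encode(), dtype="S1")
    e = np.frombuffer(seq_end.upper().encode(), dtype="S1")
    gap = GAP.encode()
    gap_any = (s == gap) | (e == gap)
    gap_both = (s == gap) & (e == gap)
    if gap_policy == "exclude":
        excluded = gap_any
    else:
        excluded = gap_both
    in_region = np.zeros(len(s), dtype=bool)
    cols = np.fromiter(region_columns, dtype=np.int64) if not isinstance(
        region_columns, np.ndarray) else region_columns
    if cols.size:
        if cols.min() < 0 or cols.max() >= len(s):
            raise ValueError("region columns outside the alignment")
        in_region[cols] = True
    differs = s != e
    use = ~excluded
    a = int(np.sum(use & in_region & differs))
    b = int(np.sum(use & in_region & ~differs))
    c = int(np.sum(use & ~in_region & differs))
    d = int(np.sum(use & ~in_region & ~differs))
    return ContingencyTable(a, b, c, d, excluded=int(excluded.sum()))


# ---------------------------------------------------------------------------
# Fisher's exact test and odds ratio
# ---------------------------------------------------------------------------

def _as_counts(table) -> tuple[int, int, int, int]:
    if isinstance(table, ContingencyTable):
        return table.as_tuple()
    a, b, c, d = table
    return int(a), int(b), int(c), int(d)


def fisher_exact(table, alternative: str = "two-sided") -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    Two-sided: the sum of probabilities of all tables with the same margins
    whose point probability does not exceed the observed one (with a tiny
    relative slack against round-off).  ``'greater'`` sums the upper tail of
    the a-cell.
    """
    a, b, c, d = _as_counts(table)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    n = a + b + c + d
    if n == 0:
        warnings.warn("all-zero contingency table; p-value is 1", RuntimeWarning)
        return 1.0
    r1, c1 = a + b, a + c
    amin, amax = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(amin, amax + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(support + 1) - gammaln(r1 - support + 1)
        + gammaln(n - r1 + 1) - gammaln(c1 - support + 1)
        - gammaln(n - r1 - c1 + support + 1)
        + gammaln(c1 + 1) + gammaln(n - c1 + 1) - gammaln(n + 1)
    )
    pmf = np.exp(logpmf)
    obs = a - amin
    if alternative == "greater":
        p = float(pmf[obs:].sum())
    elif alternative == "less":
        p = float(pmf[: obs + 1].sum())
    elif alternative == "two-sided":
        p = float(pmf[pmf <= pmf[obs] * _TWO_SIDED_SLACK].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(max(p, np.finfo(float).tiny), 1.0)


def odds_ratio(table, haldane: bool = False) -> float:
    """Sample odds ratio (a*d)/(b*c).

    Returns +inf when only the denominator product is zero and NaN when both
    products vanish (undefined).  ``haldane`` applies the +0.5 continuity
    correction to every cell instead.
    """
    a, b, c, d = _as_counts(table)
    if haldane:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    num, den = a * d, b * c
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def define_windows(
    tree: dendropy.Tree,
    ancestor_specs: Mapping[str, Iterable[str]],
) -> list[PhylogeneticWindow]:
    """Resolve named ancestors as MRCAs and join consecutive ones as windows.

    ``ancestor_specs`` maps ancestor names to leaf-taxon sets, ordered from
    the oldest (most rootward) to the most recent.  Each consecutive pair
    must be in an ancestor-descendant relationship.
    """
    name_internal_nodes(tree)
    if len(ancestor_specs) < 2:
        raise WindowError("need at least two named ancestors to form a window")
    resolved: list[tuple[str, dendropy.Node]] = []
    for name, taxa in ancestor_specs.items():
        taxa = list(taxa)
        if not taxa:
            raise WindowError(f"ancestor {name!r} has an empty taxon set")
        resolved.append((name, mrca_node(tree, taxa)))

    def depth(node: dendropy.Node) -> int:
        d = 0
        while node.parent_node is not None:
            node = node.parent_node
            d += 1
        return d

    resolved.sort(key=lambda item: depth(item[1]))
    windows = []
    for (name_a, node_a), (name_b, node_b) in zip(resolved, resolved[1:]):
        ancestors_of_b = set()
        cursor = node_b.parent_node
        while cursor is not None:
            ancestors_of_b.add(id(cursor))
            cursor = cursor.parent_node
        if id(node_a) not in ancestors_of_b:
            raise WindowError(
                f"ancestors {name_a!r} and {name_b!r} are not on one "
                "root-to-tip path"
            )
        windows.append(
            PhylogeneticWindow(
                name=f"{name_a}->{name_b}", start=node_a.label, end=node_b.label
            )
        )
    return windows


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported, not used for flags)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj


def enrichment_scan(
    sequences,
    windows: list[PhylogeneticWindow],
    region_map: RegionMap | Mapping[str, Iterable[int]],
    or_threshold: float = OR_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    gap_policy: str = "exclude",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Fisher-exact enrichment for every (region, window) combination.

    ``sequences`` is either a reconstruction results object exposing
    ``ml_sequence(node)`` or a plain mapping node -> aligned sequence.
    Returns one row per (window, region) with the full table, odds ratio,
    p-value, BH-adjusted p-value and the strict significance flag
    (OR > or_threshold and p < p_threshold).  Windows with a missing endpoint
    are reported with an ``error`` column instead of being dropped silently.
    """
    if hasattr(sequences, "ml_sequence"):
        def get_seq(node: str) -> str | None:
            try:
                return sequences.ml_sequence(node)
            except KeyError:
                return None
    else:
        mapping = dict(sequences)
        get_seq = mapping.get

    region_items = list(region_map.items())
    rows = []
    for window in windows:
        seq_start = get_seq(window.start)
        seq_end = get_seq(window.end)
        if seq_start is None or seq_end is None:
            missing = window.start if seq_start is None else window.end
            for region, _ in region_items:
                rows.append({
                    "window": window.name, "region": region,
                    "error": f"missing endpoint sequence {missing!r}",
                })
            continue
        for region, columns in region_items:
            table = count_substitutions(seq_start, seq_end, columns, gap_policy)
            orx = odds_ratio(table)
            p = fisher_exact(table, alternative)
            rows.append({
                "window": window.name, "region": region,
                "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                "excluded": table.excluded,
                "odds_ratio": orx, "p_value": p,
                "significant": bool(orx > or_threshold and p < p_threshold),
                "error": "",
            })
    df = pd.DataFrame(rows)
    if "p_value" in df:
        ok = df["error"] == ""
        df["p_bh"] = np.nan
        if ok.any():
            df.loc[ok, "p_bh"] = _bh_adjust(df.loc[ok, "p_value"].to_numpy())
    df.attrs["thresholds"] = {"odds_ratio": or_threshold, "p_value": p_threshold}
    df.attrs["gap_policy"] = gap_policy
    df.attrs["alternative"] = alternative
    return df
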