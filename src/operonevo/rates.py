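"""Alteration-rate statistics: events per 1,000 amino-acid substitutions.

A branch's substitution count is its length (substitutions/site) times the
concatenated-alignment length in columns; the rate is
``1000 * n_events / n_substitutions``.  Group summaries follow the
convention of averaging only branches that carry at least one alteration.
Printed integers (percentages, folds) use half-away-from-zero rounding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from statistics import mean, stdev

from scipy import stats as _scipy_stats

from .events import AlterationEvent
from .trees import SupportTree, branch_id, clade_leaves

logger = logging.getLogger(__name__)

__all__ = [
    "BranchRate",
    "GroupRateSummary",
    "ALIGNMENT_LENGTHS",
    "round_half_away",
    "branch_rate",
    "rates_from_events",
    "group_summary",
    "order_wide_rate",
    "fold_change",
    "compare_groups_ttest",
    "percent",
]

# concatenated-alignment lengths (amino-acid columns) by dataset tag:
# 39 proteins for the gammaproteobacterial set, 44 for the bacillal set
ALIGNMENT_LENGTHS = {"gammaproteobacteria": 9429, "bacilli": 10199}


def round_half_away(x: float) -> int:
    """Round half away from zero (the convention of printed integers here)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class BranchRate:
    branch_id: str
    n_events: int
    branch_length: float
    alignment_length: int

    @property
    def n_substitutions(self) -> float:
        return self.branch_length * self.alignment_length

    @property
    def rate_per_1000(self) -> float | None:
        """Events per 1,000 substitutions; None (flagged) on a zero-length branch."""
        if self.n_substitutions == 0:
            return None if self.n_events > 0 else 0.0
        return 1000.0 * self.n_events / self.n_substitutions


def branch_rate(n_events: int, branch_length: float, alignment_length: int) -> BranchRate:
    if n_events < 0 or branch_length < 0 or alignment_length <= 0:
        raise ValueError(
            "n_events and branch_length must be >= 0 and alignment_length > 0"
        )
    br = BranchRate("", n_events, branch_length, alignment_length)
    if br.rate_per_1000 is None:
        logger.warning(
            "branch with %d events but zero length: rate undefined", n_events
        )
    return br


def rates_from_events(
    tree: SupportTree, events: list[AlterationEvent], alignment_length: int
) -> list[BranchRate]:
    """Per-branch rates for every branch of the tree (zero-event ones included)."""
    per_branch: dict[str, int] = {}
    for ev in events:
        per_branch[ev.branch_id] = per_branch.get(ev.branch_id, 0) + 1
    out = []
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bid = branch_id(node)
        out.append(
            BranchRate(
                branch_id=bid,
                n_events=per_branch.get(bid, 0),
                branch_length=tree.branch_length(node),
                alignment_length=alignment_length,
            )
        )
    return out


@dataclass
class GroupRateSummary:
    group: str
    n: int
    mean: float
    sd: float | None  # sample sd (n-1); absent when n = 1
    rates: list[float]


def group_summary(
    rates: list[BranchRate],
    grouping: dict[str, str] | None = None,
    include_zero_event_branches: bool = False,
) -> list[GroupRateSummary]:
    """Mean +/- sd of per-branch rates per group.

    By default only branches with at least one alteration enter the average;
    branches with undefined rates (zero length, > 0 events) are excluded
    with a warning.
    """
    groups: dict[str, list[float]] = {}
    for br in rates:
        if not include_zero_event_branches and br.n_events == 0:
            continue
        r = br.rate_per_1000
        if r is None:
            logger.warning("excluding zero-length branch %s from summary", br.branch_id)
            continue
        group = grouping.get(br.branch_id, "all") if grouping else "all"
        groups.setdefault(group, []).append(r)
    out = []
    for group in sorted(groups):
        vals = groups[group]
        if not vals:
            logger.warning("group %s empty after filtering; omitted", group)
            continue
        out.append(
            GroupRateSummary(
                group=group,
                n=len(vals),
                mean=mean(vals),
                sd=stdev(vals) if len(vals) > 1 else None,
                rates=vals,
            )
        )
    return out


def order_wide_rate(
    events: list[AlterationEvent],
    tree: SupportTree,
    order_membership: dict[str, str],
    alignment_length: int,
) -> dict[str, float]:
    """Per-order alteration rate over all branches wholly inside each order.

    A branch belongs to an order when every leaf below it is a member;
    zero-event branches count toward the substitution denominator.  For a
    non-monophyletic order this picks exactly the branches of its maximal
    wholly-contained subtrees (warned about).
    """
    leaves = set(tree.leaf_names)
    missing = leaves - set(order_membership)
    if missing:
        raise ValueError(f"leaves without order assignment: {sorted(missing)}")
    events_per_branch: dict[str, int] = {}
    for ev in events:
        events_per_branch[ev.branch_id] = events_per_branch.get(ev.branch_id, 0) + 1

    orders = sorted(set(order_membership.values()))
    totals = {o: {"events": 0, "subs": 0.0} for o in orders}
    order_leafsets = {
        o: {lf for lf, oo in order_membership.items() if oo == o} for o in orders
    }
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = clade_leaves(node)
        for o in orders:
            if below <= order_leafsets[o]:
                totals[o]["events"] += events_per_branch.get(branch_id(node), 0)
                totals[o]["subs"] += tree.branch_length(node) * alignment_length
                break
    for o in orders:
        member_mrca = (
            tree.mrca(order_leafsets[o]) if len(order_leafsets[o]) > 1 else None
        )
        if member_mrca is not None and clade_leaves(member_mrca) != order_leafsets[o]:
            logger.warning(
                "order %s is not monophyletic; using its maximal wholly-contained "
                "subtrees", o,
            )
    return {
        o: (1000.0 * t["events"] / t["subs"] if t["subs"] > 0 else 0.0)
        for o, t in totals.items()
    }


def fold_change(rate_a: float, rate_b: float) -> tuple[float, int]:
    """Ratio a/b plus the printed integer fold (half-away-from-zero)."""
    if rate_b == 0:
        raise ValueError("fold change undefined: reference rate is zero")
    ratio = rate_a / rate_b
    return ratio, round_half_away(ratio)


def compare_groups_ttest(
    rates_a: list[float], rates_b: list[float], equal_var: bool = False
) -> dict[str, float]:
    """Two-sided two-sample t-test on per-branch rates (Welch by default)."""
    if len(rates_a) < 2 or len(rates_b) < 2:
        raise ValueError("each group needs at least two branches")
    res = _scipy_stats.ttest_ind(rates_a, rates_b, equal_var=equal_var)
    df = getattr(res, "df", float("nan"))
    return {"t": float(res.statistic), "df": float(df), "p": float(res.pvalue)}


def percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half away from zero (38/103 -> 37)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return round_half_away(100.0 * numerator / denominator)
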