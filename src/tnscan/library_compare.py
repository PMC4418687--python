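"""Differential analysis between two mutant libraries.

Conditionally essential genes — required under one growth condition but not
another — show up as large differences between libraries. Two arithmetics
are supported: the capped difference of essentiality indices (each EI first
capped, default 10, on the reasoning that EI at or above the cap already
means "probably not essential", so differences beyond it carry no signal),
and the selection ratio (per-gene read count under the test condition
divided by the control read count), with genes carrying too few unique
insertions in the control excluded as uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

DEFAULT_CAP = 10
DEFAULT_MIN_UNIQUE = 3


@dataclass(frozen=True)
class ComparisonRecord:
    locus_tag: str
    metric_a: Optional[float]
    metric_b: Optional[float]
    delta_ei: Optional[int] = None
    selection_ratio: Optional[float] = None
    excluded: bool = False
    reason: Optional[str] = None


@dataclass(frozen=True)
class SelectionResult:
    ratio: Optional[float]
    excluded: bool
    reason: Optional[str] = None


def capped_delta_ei(ei_a: int, ei_b: int, cap: int = DEFAULT_CAP) -> int:
    """min(ei_a, cap) - min(ei_b, cap); always within [-cap, cap]."""
    if ei_a < 0 or ei_b < 0:
        raise ValueError("EI values must be non-negative")
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    return min(int(ei_a), cap) - min(int(ei_b), cap)


def selection_ratio(
    reads_condition: int,
    reads_control: int,
    control_unique_insertions: int,
    min_unique: int = DEFAULT_MIN_UNIQUE,
) -> SelectionResult:
    """Per-gene read ratio condition/control with a control-support filter.

    Genes with fewer than ``min_unique`` unique insertions in the control
    library are excluded (their ratio would rest on too few independent
    mutants). A surviving gene with zero control reads has an undefined
    ratio, flagged rather than erroring.
    """
    if min(reads_condition, reads_control, control_unique_insertions) < 0:
        raise ValueError("read and insertion counts must be non-negative")
    if control_unique_insertions < min_unique:
        return SelectionResult(
            None, True,
            f"fewer than {min_unique} unique insertions in control "
            f"({control_unique_insertions})",
        )
    if reads_control == 0:
        return SelectionResult(None, False, "zero control reads")
    return SelectionResult(reads_condition / reads_control, False, None)


def compare_ei_tables(
    ei_a: Mapping[str, int],
    ei_b: Mapping[str, int],
    cap: int = DEFAULT_CAP,
) -> List[ComparisonRecord]:
    """Capped delta-EI for every shared gene, sorted ascending by delta.

    Negative deltas mean depletion in library a relative to b. Genes present
    in only one table are appended, flagged excluded. An empty intersection
    is an error.
    """
    shared = sorted(set(ei_a) & set(ei_b))
    if not shared:
        raise ValueError("no shared locus tags between the two tables")
    records = []
    for locus in shared:
        a, b = ei_a[locus], ei_b[locus]
        if a is None or b is None:
            records.append(ComparisonRecord(
                locus, a, b, excluded=True, reason="EI undefined"))
            continue
        records.append(ComparisonRecord(
            locus, a, b, delta_ei=capped_delta_ei(a, b, cap)))
    kept = sorted(
        (r for r in records if not r.excluded),
        key=lambda r: (r.delta_ei, r.locus_tag),
    )
    dropped = [r for r in records if r.excluded]
    for locus in sorted(set(ei_a) - set(ei_b)):
        dropped.append(ComparisonRecord(
            locus, ei_a[locus], None, excluded=True, reason="missing in b"))
    for locus in sorted(set(ei_b) - set(ei_a)):
        dropped.append(ComparisonRecord(
            locus, None, ei_b[locus], excluded=True, reason="missing in a"))
    return kept + dropped


def compare_selection_tables(
    reads_a: Mapping[str, int],
    reads_b: Mapping[str, int],
    unique_b: Mapping[str, int],
    min_unique: int = DEFAULT_MIN_UNIQUE,
    scale: Optional[Tuple[float, float]] = None,
) -> List[ComparisonRecord]:
    """Selection ratios a/b for every shared gene, sorted ascending by ratio.

    ``unique_b`` carries the control library's unique-insertion counts used
    for the minimum-support filter. Depth normalization is off by default;
    ``scale=(sa, sb)`` multiplies each side's reads before the ratio (e.g.
    inverse library totals).
    """
    shared = sorted(set(reads_a) & set(reads_b))
    if not shared:
        raise ValueError("no shared locus tags between the two tables")
    sa, sb = scale if scale is not None else (1.0, 1.0)
    kept, dropped = [], []
    for locus in shared:
        res = selection_ratio(
            reads_a[locus], reads_b[locus], unique_b.get(locus, 0), min_unique
        )
        ratio = None
        if res.ratio is not None:
            ratio = (reads_a[locus] * sa) / (reads_b[locus] * sb)
        rec = ComparisonRecord(
            locus, reads_a[locus], reads_b[locus],
            selection_ratio=ratio, excluded=res.excluded, reason=res.reason,
        )
        (dropped if res.excluded or ratio is None else kept).append(rec)
    kept.sort(key=lambda r: (r.selection_ratio, r.locus_tag))
    for locus in sorted(set(reads_a) - set(reads_b)):
        dropped.append(ComparisonRecord(
            locus, reads_a[locus], None, excluded=True, reason="missing in b"))
    for locus in sorted(set(reads_b) - set(reads_a)):
        dropped.append(ComparisonRecord(
            locus, None, reads_b[locus], excluded=True, reason="missing in a"))
    return kept + dropped


def compare_tables(
    records_a: Mapping[str, object],
    records_b: Mapping[str, object],
    metric: str = "ei",
    cap: int = DEFAULT_CAP,
    min_unique: int = DEFAULT_MIN_UNIQUE,
    unique_b: Optional[Mapping[str, int]] = None,
    scale: Optional[Tuple[float, float]] = None,
) -> List[ComparisonRecord]:
    """Dispatch to the EI-delta or selection-ratio comparison."""
    if metric == "ei":
        return compare_ei_tables(records_a, records_b, cap=cap)
    if metric == "selection_ratio":
        if unique_b is None:
            raise ValueError(
                "selection_ratio comparison needs control unique-insertion "
                "counts (unique_b)"
            )
        return compare_selection_tables(
            records_a, records_b, unique_b, min_unique=min_unique, scale=scale
        )
    raise ValueError(f"unknown comparison metric {metric!r}")


def write_comparison_table(records: Sequence[ComparisonRecord], path: str) -> None:
    def fmt(x):
        if x is None:
            return ""
        return f"{x:.4f}" if isinstance(x, float) else str(x)

    with open(path, "w", newline="\n") as fh:
        fh.write(
            "locus_tag\tmetric_a\tmetric_b\tdelta_ei\tselection_ratio\t"
            "excluded\treason\n"
        )
        for r in records:
            fh.write(
                f"{r.locus_tag}\t{fmt(r.metric_a)}\t{fmt(r.metric_b)}\t"
                f"{fmt(r.delta_ei)}\t{fmt(r.selection_ratio)}\t"
                f"{'yes' if r.excluded else 'no'}\t{r.reason or ''}\n"
            )
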