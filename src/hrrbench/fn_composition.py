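"""False-negative composition from hierarchical classification reports.

Human-sample reads that survive removal ("false negatives") are classified
taxonomically; this module parses the standard 6-column hierarchical report
format (percentage, clade reads, direct reads, rank code, taxid, indented
name — 2 spaces per level), merges reports across samples while retaining
hierarchies, and summarizes the microbial / human / unclassified breakdown.

"Microbial" is defined as classified-and-not-within-the-human-clade; the
human clade is a configurable taxid set (default: the Homo sapiens subtree,
taxid 9606). The clade-sum invariant (clade reads == direct reads + children)
is verified on parse and preserved by merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from hrrbench.read_fate import FnReadSet
from hrrbench.sequence_io import SourceClass

__all__ = [
    "TaxNode",
    "ReportTree",
    "CompositionSummary",
    "parse_report",
    "serialize_report",
    "merge_reports",
    "summarize_fn_composition",
    "ancestry_balance",
    "fn_truth_composition",
]

HUMAN_TAXID = 9606
UNCLASSIFIED_TAXID = 0


@dataclass
class TaxNode:
    """One clade row of a hierarchical classification report."""

    taxid: int
    name: str
    rank_code: str
    depth: int
    direct_reads: int
    clade_reads: int
    children: List["TaxNode"] = field(default_factory=list)

    def walk(self) -> Iterable["TaxNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def check_clade_sums(self) -> None:
        for node in self.walk():
            expect = node.direct_reads + sum(c.clade_reads for c in node.children)
            if node.clade_reads != expect:
                raise ValueError(
                    f"clade-sum violation at taxid {node.taxid} ({node.name!r}): "
                    f"clade_reads={node.clade_reads}, direct+children={expect}"
                )

    def copy(self) -> "TaxNode":
        return TaxNode(
            self.taxid,
            self.name,
            self.rank_code,
            self.depth,
            self.direct_reads,
            self.clade_reads,
            [c.copy() for c in self.children],
        )


@dataclass
class ReportTree:
    """A parsed report: the classified root forest plus the unclassified row."""

    roots: List[TaxNode] = field(default_factory=list)
    unclassified_reads: int = 0

    @property
    def classified_reads(self) -> int:
        return sum(r.clade_reads for r in self.roots)

    @property
    def total_reads(self) -> int:
        return self.classified_reads + self.unclassified_reads

    def walk(self) -> Iterable[TaxNode]:
        for root in self.roots:
            yield from root.walk()

    def flat_counts(self) -> Dict[int, Tuple[int, int]]:
        """taxid → (direct_reads, clade_reads), summed over occurrences."""
        out: Dict[int, Tuple[int, int]] = {}
        for node in self.walk():
            d, c = out.get(node.taxid, (0, 0))
            out[node.taxid] = (d + node.direct_reads, c + node.clade_reads)
        return out


@dataclass(frozen=True)
class CompositionSummary:
    """Microbial / human / unclassified breakdown of one FN read set."""

    cell: Optional[str]
    n_fn_total: int
    n_microbial: int
    n_human_classified: int
    n_unclassified: int

    @property
    def pct_microbial(self) -> float:
        return 100.0 * self.n_microbial / self.n_fn_total if self.n_fn_total else 0.0


def parse_report(
    source: Union[Path, str, Sequence[str]],
    indent: int = 2,
    cell: Optional[str] = None,
) -> ReportTree:
    """Parse a 6-column hierarchical classification report into a tree.

    The tree is reconstructed from name indentation (``indent`` spaces per
    level; tab-indented dialects parse with ``indent=1`` after substituting
    tabs). The "unclassified" root row (taxid 0) is captured separately.
    Indentation jumps of more than one level and clade-sum violations raise.
    """
    if isinstance(source, Path):
        lines = source.read_text().splitlines()
    elif isinstance(source, str):
        # a string is report content when it contains structure, else a path
        if "\t" in source or "\n" in source or source == "":
            lines = source.splitlines()
        else:
            lines = Path(source).read_text().splitlines()
    else:
        lines = list(source)

    tree = ReportTree()
    stack: List[TaxNode] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"line {lineno}: expected 6 tab-separated columns, got {len(parts)}")
        _pct, clade_s, direct_s, rank_code, taxid_s, padded_name = parts
        clade_reads, direct_reads, taxid = int(clade_s), int(direct_s), int(taxid_s)
        stripped = padded_name.lstrip(" ")
        pad = len(padded_name) - len(stripped)
        if pad % indent != 0:
            raise ValueError(f"line {lineno}: indentation {pad} is not a multiple of {indent}")
        depth = pad // indent

        if taxid == UNCLASSIFIED_TAXID and depth == 0:
            tree.unclassified_reads += clade_reads
            continue
        node = TaxNode(taxid, stripped, rank_code, depth, direct_reads, clade_reads)
        if depth == 0:
            tree.roots.append(node)
            stack = [node]
            continue
        if depth > len(stack):
            raise ValueError(
                f"line {lineno}: indentation jumps from level {len(stack) - 1} to {depth}"
            )
        del stack[depth:]
        if not stack:
            raise ValueError(f"line {lineno}: child row with no parent")
        stack[-1].children.append(node)
        stack.append(node)

    for root in tree.roots:
        root.check_clade_sums()
    return tree


def serialize_report(tree: ReportTree, indent: int = 2) -> str:
    """Write a tree back to the 6-column dialect (percentages recomputed)."""
    total = tree.total_reads
    lines: List[str] = []

    def pct(reads: int) -> str:
        return f"{100.0 * reads / total:.2f}" if total else "0.00"

    if tree.unclassified_reads or not tree.roots:
        lines.append(
            "\t".join(
                [
                    pct(tree.unclassified_reads),
                    str(tree.unclassified_reads),
                    str(tree.unclassified_reads),
                    "U",
                    str(UNCLASSIFIED_TAXID),
                    "unclassified",
                ]
            )
        )

    def emit(node: TaxNode) -> None:
        lines.append(
            "\t".join(
                [
                    pct(node.clade_reads),
                    str(node.clade_reads),
                    str(node.direct_reads),
                    node.rank_code,
                    str(node.taxid),
                    " " * (indent * node.depth) + node.name,
                ]
            )
        )
        for child in node.children:
            emit(child)

    for root in tree.roots:
        emit(root)
    return "\n".join(lines) + ("\n" if lines else "")


def _merge_children(
    target: List[TaxNode], source: List[TaxNode], path: Tuple[int, ...]
) -> None:
    index = {c.taxid: c for c in target}
    for child in source:
        if child.taxid in index:
            node = index[child.taxid]
            if node.name != child.name or node.rank_code != child.rank_code:
                raise ValueError(
                    f"taxid {child.taxid} has conflicting identity under path {path}: "
                    f"{(node.name, node.rank_code)} vs {(child.name, child.rank_code)}"
                )
            node.direct_reads += child.direct_reads
            node.clade_reads += child.clade_reads
            _merge_children(node.children, child.children, path + (child.taxid,))
        else:
            cp = child.copy()
            target.append(cp)
            index[child.taxid] = cp


def _check_unique_paths(tree: ReportTree) -> None:
    paths: Dict[int, Tuple[int, ...]] = {}

    def visit(node: TaxNode, path: Tuple[int, ...]) -> None:
        here = path + (node.taxid,)
        if node.taxid in paths and paths[node.taxid] != here:
            raise ValueError(
                f"taxid {node.taxid} appears at conflicting paths "
                f"{paths[node.taxid]} and {here}"
            )
        paths[node.taxid] = here
        for child in node.children:
            visit(child, here)

    for root in tree.roots:
        visit(root, ())


def merge_reports(trees: Sequence[ReportTree]) -> ReportTree:
    """Merge counts across samples retaining hierarchies.

    Nodes are unioned keyed by (path, taxid); direct and clade counts sum, so
    merge is associative and commutative on count content and preserves the
    clade-sum invariant. A taxid sitting at conflicting paths raises with
    both paths.
    """
    merged = ReportTree()
    for tree in trees:
        merged.unclassified_reads += tree.unclassified_reads
        _merge_children(merged.roots, tree.roots, ())
    _check_unique_paths(merged)
    for root in merged.roots:
        root.check_clade_sums()
    return merged


def summarize_fn_composition(
    tree: ReportTree,
    human_taxids: Set[int] = frozenset({HUMAN_TAXID}),
    cell: Optional[str] = None,
) -> CompositionSummary:
    """Breakdown of a classified FN read set into microbial / human /
    unclassified, where microbial = classified and not within any human-clade
    taxid. Nested human taxids are counted once at the outermost node
    (clade-level accounting prevents double counts)."""
    n_human = 0

    def visit(node: TaxNode) -> None:
        nonlocal n_human
        if node.taxid in human_taxids:
            n_human += node.clade_reads
            return  # whole subtree already counted
        for child in node.children:
            visit(child)

    for root in tree.roots:
        visit(root)
    total = tree.total_reads
    n_unc = tree.unclassified_reads
    n_microbial = total - n_human - n_unc
    return CompositionSummary(cell, total, n_microbial, n_human, n_unc)


def fn_truth_composition(fn_set: FnReadSet) -> Dict[str, int]:
    """Classifier-free composition of an FN set from provenance truth alone:
    counts of genuinely-host vs contaminant reads among the false negatives."""
    census = fn_set.class_census()
    return {
        "host": census.get(SourceClass.HOST, 0),
        "contaminant": census.get(SourceClass.CONTAMINANT, 0),
    }


@dataclass(frozen=True)
class AncestryBalanceResult:
    counts: "pd.Series"
    expected: "pd.Series"
    statistic: float
    p_value: float
    method: str


def ancestry_balance(
    fn_set: FnReadSet,
    donor_groups: Mapping[str, str],
    n_simulations: int = 2000,
    seed: int = 0,
    min_expected_exact: float = 5.0,
) -> Optional[AncestryBalanceResult]:
    """Test whether FN reads are biased toward particular donor groups.

    The null expectation is proportional to the number of donors per group
    (donors contribute host reads with identical frequency by design).
    Pearson chi-square statistic; p from the asymptotic chi-square law when
    all expected counts are large, otherwise from a seeded Monte Carlo
    multinomial simulation with the add-one rule. Empty FN set → None.
    """
    from scipy import stats as sps

    donor_census = fn_set.donor_census()
    unmapped = sorted(set(donor_census) - set(donor_groups))
    if unmapped:
        raise ValueError(f"FN donors with no group mapping: {unmapped}")
    if not donor_census:
        return None

    groups = sorted(set(donor_groups.values()))
    donors_per_group = pd.Series(
        {g: sum(1 for v in donor_groups.values() if v == g) for g in groups}, dtype=float
    )
    counts = pd.Series(0, index=groups, dtype=float)
    for donor, n in donor_census.items():
        counts[donor_groups[donor]] += n
    total = counts.sum()
    expected = donors_per_group / donors_per_group.sum() * total

    stat = float(((counts - expected) ** 2 / expected).sum())
    if (expected >= min_expected_exact).all():
        p = float(sps.chi2.sf(stat, df=len(groups) - 1))
        method = "chi2"
    else:
        rng = np.random.default_rng(seed)
        probs = (donors_per_group / donors_per_group.sum()).to_numpy()
        sims = rng.multinomial(int(total), probs, size=n_simulations)
        exp = expected.to_numpy()
        stats_sim = ((sims - exp) ** 2 / exp).sum(axis=1)
        p = float((1 + (stats_sim >= stat - 1e-12).sum()) / (1 + n_simulations))
        method = "monte-carlo"
    return AncestryBalanceResult(counts, expected, stat, p, method)
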