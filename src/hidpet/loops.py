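"""Turn raw contact lists into a cell line's final enhancer-promoter loop set.

The upstream steps of a ChIA-PET experiment (linker filtering, mapping,
self/inter-ligation classification, peak calling) are out of scope: the
input here is already a list of anchored contacts with tag counts.  This
module annotates anchors with chromatin-state labels, keeps contacts
whose two anchors carry enhancer-class and promoter-class states with
more than ``min_tags`` supporting tags, and merges duplicate contacts
across antibodies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .formats import IntervalSet, Loop

log = logging.getLogger(__name__)

#: Substrings that qualify a chromatin-state label as enhancer- or
#: promoter-class.  Segmentation vocabularies differ between cell lines
#: (e.g. "Strong_Enhancer", "Active_Promoter", "TssA"), so matching is
#: by substring against configurable lists.
DEFAULT_ENHANCER_LABELS = ("Enhancer", "Enh")
DEFAULT_PROMOTER_LABELS = ("Promoter", "Prom", "TSS", "Tss")


@dataclass
class LoopSet:
    """The final contact list of one cell line, post filtering/merging."""

    cell_line: str
    loops: list[Loop] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self):
        return iter(self.loops)


def annotate_anchors(loops: list[Loop], states: IntervalSet) -> list[Loop]:
    """Attach to each anchor the labels of all state segments overlapping it.

    Overlap is >= 1 bp on the half-open convention.  Anchors on
    chromosomes absent from the segmentation get an empty label set (a
    warning is logged once per chromosome).
    """
    warned: set[str] = set()
    out = []
    for lp in loops:
        labels = []
        for anchor in (lp.anchor_a, lp.anchor_b):
            hits = states.overlapping(anchor)
            if not hits and anchor.chrom not in states.chroms and anchor.chrom not in warned:
                warned.add(anchor.chrom)
                log.warning("chromosome %s absent from state segmentation", anchor.chrom)
            labels.append(frozenset(h.label for h in hits if h.label is not None))
        out.append(replace(lp, states_a=labels[0], states_b=labels[1]))
    return out


def _matches(labels: frozenset[str], vocab: tuple[str, ...]) -> bool:
    return any(v in lab for lab in labels for v in vocab)


def is_ep_loop(
    loop: Loop,
    enhancer_labels: tuple[str, ...] = DEFAULT_ENHANCER_LABELS,
    promoter_labels: tuple[str, ...] = DEFAULT_PROMOTER_LABELS,
) -> bool:
    """True iff one anchor carries an enhancer-class state and the other a
    promoter-class state (either assignment of anchors to roles counts)."""
    a, b = loop.states_a, loop.states_b
    return (_matches(a, enhancer_labels) and _matches(b, promoter_labels)) or (
        _matches(b, enhancer_labels) and _matches(a, promoter_labels)
    )


def enhancer_promoter_anchors(
    loop: Loop,
    enhancer_labels: tuple[str, ...] = DEFAULT_ENHANCER_LABELS,
    promoter_labels: tuple[str, ...] = DEFAULT_PROMOTER_LABELS,
):
    """Resolve which anchor plays the enhancer and which the promoter.

    Returns ``(enhancer_anchor, promoter_anchor)`` or ``None`` if the
    loop is not an EP loop.  When both assignments qualify (both anchors
    carry both state classes) anchor_a is taken as the enhancer.
    """
    a_enh = _matches(loop.states_a, enhancer_labels)
    a_pro = _matches(loop.states_a, promoter_labels)
    b_enh = _matches(loop.states_b, enhancer_labels)
    b_pro = _matches(loop.states_b, promoter_labels)
    if a_enh and b_pro:
        return loop.anchor_a, loop.anchor_b
    if b_enh and a_pro:
        return loop.anchor_b, loop.anchor_a
    return None


def filter_ep_loops(
    loops: list[Loop],
    cell_line: str = "",
    min_tags: int = 5,
    enhancer_labels: tuple[str, ...] = DEFAULT_ENHANCER_LABELS,
    promoter_labels: tuple[str, ...] = DEFAULT_PROMOTER_LABELS,
) -> LoopSet:
    """Keep annotated loops with concurrent enhancer/promoter anchors and
    strictly more than ``min_tags`` supporting tags (default: tags >= 6)."""
    kept = [
        lp
        for lp in loops
        if lp.tags > min_tags and is_ep_loop(lp, enhancer_labels, promoter_labels)
    ]
    return LoopSet(cell_line, kept)


def merge_contacts(loopsets: list[LoopSet]) -> LoopSet:
    """Combine per-antibody contact lists of one cell line.

    Loops with identical anchor coordinate pairs collapse to a single
    record whose tag count is the sum of the merged tags and whose state
    label sets are unioned.  Commutative and associative.
    """
    if not loopsets:
        raise ValueError("no loop sets to merge")
    names = {ls.cell_line for ls in loopsets}
    if len(names) > 1:
        raise ValueError(f"refusing to merge loop sets from different cell lines: {sorted(names)}")
    merged: dict[tuple, Loop] = {}
    for ls in loopsets:
        for lp in ls:
            key = lp.coords
            if key in merged:
                prev = merged[key]
                merged[key] = replace(
                    prev,
                    tags=prev.tags + lp.tags,
                    states_a=prev.states_a | lp.states_a,
                    states_b=prev.states_b | lp.states_b,
                )
            else:
                merged[key] = lp
    return LoopSet(names.pop(), sorted(merged.values(), key=lambda l: l.coords))
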