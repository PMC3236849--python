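"""Cumulative specificity and coverage of ranked alignments against annotations.

For the i-th alignment, over its fully matched steps ``(u, v)``: the step is
*annotated* when both nodes carry a group entry (count ``b_i``) and *correct*
when the groups also agree (count ``a_i``). Cumulative specificity of the top
k alignments is

    cs_k = (sum_{i<=k} a_i) / (sum_{i<=k} b_i),

undefined (``None``, not 0) when the denominator is 0, and cumulative coverage
``cc_k = sum_{i<=k} a_i`` counts correct pairs with multiplicity across
alignments. Gap steps and pairs with an unannotated side affect neither count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from .align import PathAlignment
from .network_io import AnnotationMap


@dataclass
class EvalSeries:
    """Per-rank correct/annotated counts and their cumulative ratios."""

    a: List[int]  # correct aligned pairs per alignment
    b: List[int]  # annotated aligned pairs per alignment
    cs: List[Optional[float]]  # cumulative specificity, None where undefined
    cc: List[int]  # cumulative coverage

    def __len__(self) -> int:
        return len(self.a)


def evaluate_alignments(
    alignments: Sequence[PathAlignment], ann1: AnnotationMap, ann2: AnnotationMap
) -> EvalSeries:
    """Score a ranked alignment list against two annotation maps."""
    a: List[int] = []
    b: List[int] = []
    for aln in alignments:
        correct = annotated = 0
        for u, v in aln.matched_pairs():
            g1, g2 = ann1.get(u), ann2.get(v)
            if g1 is None or g2 is None:
                continue
            annotated += 1
            if g1 == g2:
                correct += 1
        a.append(correct)
        b.append(annotated)
    cs: List[Optional[float]] = []
    cc: List[int] = []
    ca = cb = 0
    for ai, bi in zip(a, b):
        ca += ai
        cb += bi
        cs.append(ca / cb if cb > 0 else None)
        cc.append(ca)
    return EvalSeries(a=a, b=b, cs=cs, cc=cc)


def write_eval_series(series: EvalSeries, path: str) -> None:
    """TSV with columns k, a_cum, b_cum, cs_k, cc_k (cs ``NA`` where undefined)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# k\ta_cum\tb_cum\tcs_k\tcc_k\n")
        ca = cb = 0
        for k, (ai, bi) in enumerate(zip(series.a, series.b), start=1):
            ca += ai
            cb += bi
            cs = "NA" if series.cs[k - 1] is None else f"{series.cs[k - 1]:.6f}"
            fh.write(f"{k}\t{ca}\t{cb}\t{cs}\t{series.cc[k - 1]}\n")
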