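"""Coevolutionary features: column mutual information at ten alignment
depths.

For a substitution at query position ``p``, MI (bits) is computed between
the alignment column holding ``p`` and the columns holding the eight
neighbouring positions (offsets -4..-1, +1..+4), in alignments built from
N = 100..1000 (step 100) homologs.  Per depth the eight positional MI
values, their min/max/mean, and eleven parallel binary gap indicators give
22 features; ten depths give 220.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

from ..records import AA_SET, Msa, SaasError, SaasRecord

DEFAULT_DEPTHS: Tuple[int, ...] = tuple(range(100, 1001, 100))
OFFSETS: Tuple[int, ...] = (-4, -3, -2, -1, 1, 2, 3, 4)


@dataclass(frozen=True)
class JointColumnProfile:
    """Joint residue counts for two alignment columns.

    Rows with a gap (or X) in either column are excluded pairwise;
    ``n_excluded`` records how many were dropped.
    """

    joint_counts: Mapping[Tuple[str, str], int]
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return sum(self.joint_counts.values())

    def marginals(self) -> Tuple[Dict[str, float], Dict[str, float]]:
        n = self.n
        pa: Dict[str, float] = {}
        pb: Dict[str, float] = {}
        for (a, b), c in self.joint_counts.items():
            pa[a] = pa.get(a, 0.0) + c / n
            pb[b] = pb.get(b, 0.0) + c / n
        return pa, pb


def joint_profile(msa: Msa, col_i: int, col_j: int) -> JointColumnProfile:
    """Pairwise-complete joint counts for two 1-based alignment columns."""
    counts: Dict[Tuple[str, str], int] = {}
    excluded = 0
    for row in msa.rows:
        a, b = row[col_i - 1], row[col_j - 1]
        if a in AA_SET and b in AA_SET:
            counts[(a, b)] = counts.get((a, b), 0) + 1
        else:
            excluded += 1
    return JointColumnProfile(joint_counts=counts, n_excluded=excluded)


def mutual_information(joint: JointColumnProfile) -> float:
    """MI in bits: sum over residue pairs of P(a,b) log2(P(a,b)/(P(a)P(b))).

    Zero-probability terms contribute 0; an empty profile (no gap-free row
    pair) yields 0.
    """
    n = joint.n
    if n == 0:
        return 0.0
    pa, pb = joint.marginals()
    mi = 0.0
    for (a, b), c in joint.joint_counts.items():
        pab = c / n
        mi += pab * math.log2(pab / (pa[a] * pb[b]))
    return max(mi, 0.0)


def coevo_feature_names(depths: Sequence[int] = DEFAULT_DEPTHS) -> List[str]:
    """Deterministic feature-name order: per depth, 8 positional MI values,
    MIN/MAX/MEAN, then the matching gap indicators."""
    names: List[str] = []
    for n in depths:
        tags = [f"P{o:+d}".replace("+", "p").replace("-", "m") for o in OFFSETS]
        tags += ["MIN", "MAX", "MEAN"]
        names.extend(f"MI_N{n}_{t}" for t in tags)
        names.extend(f"GAP_N{n}_{t}" for t in tags)
    return names


def coevolution_vector(msa_by_depth: Mapping[int, Msa], saas: SaasRecord,
                       depths: Sequence[int] = DEFAULT_DEPTHS,
                       ) -> Dict[str, float]:
    """All coevolutionary features for one substitution.

    ``msa_by_depth`` maps each configured depth N to an alignment built from
    (up to) N homologs; a depth with fewer available rows uses all rows.
    Offsets falling outside the protein get MI 0 and gap indicator 1.
    """
    if not msa_by_depth:
        raise SaasError("empty depth map")
    out: Dict[str, float] = {}
    for n in depths:
        if n not in msa_by_depth:
            raise SaasError(f"no alignment provided for depth {n}")
        msa = msa_by_depth[n]
        qlen = len(msa.query_sequence)
        col_i = msa.column_of_query_position(saas.position)
        mis: List[float] = []
        gaps: List[float] = []
        for off in OFFSETS:
            pos_j = saas.position + off
            if not (1 <= pos_j <= qlen):
                mis.append(0.0)
                gaps.append(1.0)
                continue
            col_j = msa.column_of_query_position(pos_j)
            joint = joint_profile(msa, col_i, col_j)
            mis.append(mutual_information(joint))
            gaps.append(1.0 if joint.n_excluded > 0 else 0.0)
        tags = [f"P{o:+d}".replace("+", "p").replace("-", "m") for o in OFFSETS]
        for t, v, g in zip(tags, mis, gaps):
            out[f"MI_N{n}_{t}"] = v
            out[f"GAP_N{n}_{t}"] = g
        out[f"MI_N{n}_MIN"] = min(mis)
        out[f"MI_N{n}_MAX"] = max(mis)
        out[f"MI_N{n}_MEAN"] = sum(mis) / len(mis)
        any_gap = 1.0 if any(g == 1.0 for g in gaps) else 0.0
        out[f"GAP_N{n}_MIN"] = any_gap
        out[f"GAP_N{n}_MAX"] = any_gap
        out[f"GAP_N{n}_MEAN"] = any_gap
    # reorder to the canonical name order
    return {name: out[name] for name in coevo_feature_names(depths)}
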