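"""Subfamily typing from the internal-deletion signature and chromatin-domain
assignment from flank annotation plus phylogenetic clusterization.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._align import global_align
from .phylo import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class SubfamilyCall:
    monomer_id: str
    label: str  # F360 | F190 | other
    deletion: tuple[int, int] | None  # reference-consensus coordinates
    canonical_deletion: bool


@dataclass
class ChromatinCall:
    array_id: str
    label: str  # heterochromatic | euchromatic | unassigned
    evidence: str | None  # flank | cluster | both | None
    details: dict = field(default_factory=dict)


def call_subfamily(
    monomer_id: str,
    sequence: str,
    reference_360: str,
    min_del: int = 100,
) -> SubfamilyCall:
    """Type a monomer as F360/F190/other against the full-length consensus.

    The monomer is globally aligned to the reference; the longest contiguous
    gap run in the monomer row is the candidate deletion.  F190 requires a
    gap run >= ``min_del`` and a monomer length in [150, 260]; F360 requires
    length in [300, 420] and no large gap run.  The deletion is canonical
    when its midpoint lies in the central third of the reference.
    """
    seq = sequence.upper()
    ref = reference_360.upper()
    a_ref, a_seq, _ = global_align(ref, seq)

    # longest '-' run in the monomer row, in reference coordinates
    best_run = (0, None, None)  # (length, ref_start, ref_end)
    run_start = None
    ref_pos = 0
    for rc, sc in zip(a_ref, a_seq):
        if sc == "-" and rc != "-":
            if run_start is None:
                run_start = ref_pos
        elif rc != "-":
            if run_start is not None and ref_pos - run_start > best_run[0]:
                best_run = (ref_pos - run_start, run_start, ref_pos)
            run_start = None
        if rc != "-":
            ref_pos += 1
    if run_start is not None and ref_pos - run_start > best_run[0]:
        best_run = (ref_pos - run_start, run_start, ref_pos)

    gap_len, del_start, del_end = best_run
    mono_len = len(seq)
    deletion = (del_start, del_end) if gap_len >= min_del else None
    if deletion is not None and 150 <= mono_len <= 260:
        label = "F190"
    elif 300 <= mono_len <= 420 and gap_len < min_del:
        label = "F360"
    else:
        label = "other"
    canonical = False
    if deletion is not None:
        mid = (deletion[0] + deletion[1]) / 2.0
        canonical = len(ref) / 3.0 <= mid <= 2.0 * len(ref) / 3.0
    return SubfamilyCall(
        monomer_id=monomer_id,
        label=label,
        deletion=deletion,
        canonical_deletion=canonical,
    )


def _interval_overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _coverage_fraction(win_start, win_end, intervals) -> float:
    """Fraction of [win_start, win_end) covered by the union of intervals."""
    if win_end <= win_start:
        return 1.0
    clipped = sorted(
        (max(s, win_start), min(e, win_end))
        for s, e in intervals
        if _interval_overlap(s, e, win_start, win_end) > 0
    )
    covered = 0
    cursor = win_start
    for s, e in clipped:
        s = max(s, cursor)
        if e > s:
            covered += e - s
            cursor = e
    return covered / (win_end - win_start)


def assign_chromatin_by_flank(
    array_id: str,
    interval: tuple[int, int],
    scaffold_length: int,
    genes: list[tuple[str, int, int]],
    repeats: list[tuple[int, int]],
    flank_bp: int = 1000,
    het_cov: float = 0.80,
) -> ChromatinCall:
    """Label an array from its flanking annotation.

    Euchromatic when any gene overlaps either flank window; heterochromatic
    when >= ``het_cov`` of both flanks is covered by repeat intervals and no
    gene overlaps; otherwise unassigned.  ``genes`` are (gene_id, start,
    end); ``repeats`` are other repeat intervals on the same scaffold
    (the array itself is ignored).  Arrays at scaffold edges use one-sided
    flanks.
    """
    if not 500 <= flank_bp <= 2000:
        raise ValueError("flank_bp must be within [500, 2000]")
    start, end = interval
    if not (0 <= start < end <= scaffold_length):
        raise ValueError(f"array {array_id} outside scaffold bounds")
    left = (max(0, start - flank_bp), start)
    right = (end, min(scaffold_length, end + flank_bp))
    if left[1] - left[0] < flank_bp or right[1] - right[0] < flank_bp:
        logger.info("array %s at scaffold edge: one-sided flanks used", array_id)

    flank_genes = [
        gid
        for gid, gs, ge in genes
        if _interval_overlap(gs, ge, *left) > 0 or _interval_overlap(gs, ge, *right) > 0
    ]
    if flank_genes:
        return ChromatinCall(
            array_id=array_id,
            label="euchromatic",
            evidence="flank",
            details={"genes": flank_genes},
        )
    reps = [(s, e) for s, e in repeats if (s, e) != (start, end)]
    cov_left = _coverage_fraction(*left, reps)
    cov_right = _coverage_fraction(*right, reps)
    if cov_left >= het_cov and cov_right >= het_cov:
        return ChromatinCall(
            array_id=array_id,
            label="heterochromatic",
            evidence="flank",
            details={"flank_repeat_coverage": (cov_left, cov_right)},
        )
    return ChromatinCall(array_id=array_id, label="unassigned", evidence=None)


def assign_chromatin_by_cluster(
    dm: DistanceMatrix,
    array_of: dict[str, str],
    anchors: dict[str, str],
    cut: float = 0.15,
    centroid_margin: float = 0.05,
) -> list[ChromatinCall]:
    """Propagate flank-anchored chromatin labels through average-linkage
    clusters of the monomer distance matrix.

    ``array_of`` maps monomer label -> array id; ``anchors`` maps array id ->
    "heterochromatic"/"euchromatic".  Clusters inherit the majority anchor
    label (tie -> unassigned); anchor-free clusters take the label of the
    nearer labelled cluster centroid when the margin is at least
    ``centroid_margin``.  Per-array label is the majority over its monomers.
    Output order follows sorted array ids (input-order invariant).
    """
    if not anchors:
        raise ValueError("no anchors provided")
    order = np.argsort(np.array(dm.labels, dtype=object))
    labels = [dm.labels[i] for i in order]
    mat = dm.matrix[np.ix_(order, order)]
    if np.isnan(mat).any():
        finite = mat[~np.isnan(mat)]
        fill = float(finite.max()) if finite.size else 1.0
        mat = np.where(np.isnan(mat), fill, mat)
        np.fill_diagonal(mat, 0.0)

    link = linkage(squareform(mat, checks=False), method="average")
    assignment = fcluster(link, t=cut, criterion="distance")

    cluster_ids = sorted(set(assignment))
    members = {cid: [i for i, a in enumerate(assignment) if a == cid] for cid in cluster_ids}

    cluster_label: dict[int, str | None] = {}
    for cid in cluster_ids:
        votes = Counter(
            anchors[array_of[labels[i]]]
            for i in members[cid]
            if array_of[labels[i]] in anchors
        )
        if not votes:
            cluster_label[cid] = None
        else:
            top = votes.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                cluster_label[cid] = "unassigned"
            else:
                cluster_label[cid] = top[0][0]

    # label anchor-free clusters by nearest labelled centroid
    labelled = [cid for cid in cluster_ids if cluster_label[cid] not in (None, "unassigned")]
    for cid in cluster_ids:
        if cluster_label[cid] is not None:
            continue
        if not labelled:
            cluster_label[cid] = "unassigned"
            continue
        best_by_label: dict[str, float] = {}
        for other in labelled:
            block = mat[np.ix_(members[cid], members[other])]
            dist = float(block.mean())
            lab = cluster_label[other]
            if dist < best_by_label.get(lab, math.inf):
                best_by_label[lab] = dist
        ranked = sorted(best_by_label.items(), key=lambda kv: kv[1])
        if len(ranked) == 1 or ranked[1][1] - ranked[0][1] >= centroid_margin:
            cluster_label[cid] = ranked[0][0]
        else:
            cluster_label[cid] = "unassigned"

    # per-array majority over monomer cluster labels
    per_array_votes: dict[str, Counter] = {}
    per_array_clusters: dict[str, set] = {}
    for i, lab in enumerate(labels):
        arr = array_of[lab]
        per_array_votes.setdefault(arr, Counter())[cluster_label[assignment[i]]] += 1
        per_array_clusters.setdefault(arr, set()).add(int(assignment[i]))

    calls = []
    for arr in sorted(per_array_votes):
        votes = per_array_votes[arr]
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            label = "unassigned"
        else:
            label = top[0][0]
        calls.append(
            ChromatinCall(
                array_id=arr,
                label=label,
                evidence="cluster" if label != "unassigned" else None,
                details={"clusters": sorted(per_array_clusters[arr])},
            )
        )
    return calls


def reconcile_calls(
    flank: ChromatinCall | None, cluster: ChromatinCall | None
) -> ChromatinCall:
    """Merge flank and cluster evidence; flank wins on conflict (logged)."""
    if flank is None and cluster is None:
        raise ValueError("no calls to reconcile")
    if flank is None or flank.label == "unassigned":
        return cluster if cluster is not None else flank
    if cluster is None or cluster.label == "unassigned":
        return flank
    if flank.label == cluster.label:
        return ChromatinCall(
            array_id=flank.array_id,
            label=flank.label,
            evidence="both",
            details={**cluster.details, **flank.details},
        )
    logger.warning(
        "array %s: flank says %s, cluster says %s; keeping flank",
        flank.array_id,
        flank.label,
        cluster.label,
    )
    return flank
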