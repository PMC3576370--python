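"""Dataset construction rules: redundancy reduction and hub labelling.

Redundancy reduction follows the CD-HIT-style convention: greedy incremental
clustering, longest sequence first, where a sequence joins the first cluster
whose founding representative it matches at >= 50% identity over >= 80% of
the (by default shorter) sequence's length.

The labelling rules encode two hub conventions used by different corpora:
a conservative band (>5 partners hub, <3 non-hub, 3-5 excluded) for
hub/non-hub training data, and a plain >=5 cutoff for the structural
(singlish- vs multi-interface) and kinetic (date vs party) hub classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .homology import make_aligner
from .sequence_io import ProteinRecord


@dataclass
class ClusteringResult:
    clusters: list[list[str]]
    representatives: list[str]
    params: dict

    def membership(self) -> dict[str, int]:
        return {m: i for i, cluster in enumerate(self.clusters) for m in cluster}


_ALIGNER = None


def _aligner():
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = make_aligner()
    return _ALIGNER


def pairwise_identity(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    *,
    coverage_denominator: str = "shorter",
) -> tuple[float, float]:
    """Identity and coverage of the best deterministic local alignment.

    Identity is matching columns / total alignment columns (gap columns
    included).  Coverage is the aligned span on the denominator sequence
    divided by its length; the denominator is the shorter sequence by
    default ("longer" and "query" are selectable).
    """
    res_a = a if isinstance(a, str) else a.residues
    res_b = b if isinstance(b, str) else b.residues
    alignment = _aligner().align(res_a, res_b)[0]
    blocks_a, blocks_b = alignment.aligned
    matches = 0
    aligned_residue_cols = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        aligned_residue_cols += a1 - a0
        matches += sum(res_a[i] == res_b[j] for i, j in zip(range(a0, a1), range(b0, b1)))
    if aligned_residue_cols == 0:
        return 0.0, 0.0
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    # total columns = residue columns plus gap columns inside the local span
    gap_cols = (span_a - aligned_residue_cols) + (span_b - aligned_residue_cols)
    columns = aligned_residue_cols + gap_cols
    identity = matches / columns
    if coverage_denominator == "shorter":
        denom_len, span = (
            (len(res_a), span_a) if len(res_a) <= len(res_b) else (len(res_b), span_b)
        )
    elif coverage_denominator == "longer":
        denom_len, span = (
            (len(res_a), span_a) if len(res_a) >= len(res_b) else (len(res_b), span_b)
        )
    elif coverage_denominator == "query":
        denom_len, span = len(res_a), span_a
    else:
        raise ValueError(f"unknown coverage_denominator {coverage_denominator!r}")
    return identity, span / denom_len


def reduce_redundancy(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 0.5,
    coverage_threshold: float = 0.8,
    seed: int = 0,
    *,
    coverage_denominator: str = "shorter",
) -> ClusteringResult:
    """Greedy representative-linkage clustering, longest sequence first.

    Each record joins the first existing cluster whose *founding* member it
    matches at both thresholds, otherwise it founds a new cluster.  After
    clustering, one representative per cluster is redrawn uniformly with the
    given seed.
    """
    if not records:
        raise ValueError("no records to cluster")
    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    founders: list[ProteinRecord] = []
    clusters: list[list[str]] = []
    for rec in ordered:
        placed = False
        for idx, founder in enumerate(founders):
            ident, cov = pairwise_identity(
                rec, founder, coverage_denominator=coverage_denominator
            )
            if ident >= identity_threshold and cov >= coverage_threshold:
                clusters[idx].append(rec.id)
                placed = True
                break
        if not placed:
            founders.append(rec)
            clusters.append([rec.id])
    rng = np.random.default_rng(seed)
    representatives = [cluster[int(rng.integers(len(cluster)))] for cluster in clusters]
    return ClusteringResult(
        clusters=clusters,
        representatives=representatives,
        params={
            "identity_threshold": identity_threshold,
            "coverage_threshold": coverage_threshold,
            "coverage_denominator": coverage_denominator,
            "seed": seed,
        },
    )


def write_clusters(result: ClusteringResult, path) -> None:
    """Cluster membership TSV: member_id, cluster_id, representative flag."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("member_id\tcluster_id\tis_representative\n")
        for idx, cluster in enumerate(result.clusters):
            for member in cluster:
                rep = int(member == result.representatives[idx])
                fh.write(f"{member}\t{idx}\t{rep}\n")


# ---------------------------------------------------------------------------
# Labelling thresholds
# ---------------------------------------------------------------------------


def label_hub_banded(n_partners: int) -> str:
    """Conservative hub labelling with an excluded band.

    More than five partners -> hub; fewer than three -> non_hub; three to
    five -> excluded (too close to the arbitrary cutoff to label reliably).
    """
    if n_partners < 0:
        raise ValueError("partner count must be non-negative")
    if n_partners > 5:
        return "hub"
    if n_partners < 3:
        return "non_hub"
    return "excluded"


# spec name for the banded rule
label_hub_dataset2 = label_hub_banded


def label_interface_class(n_mutually_exclusive_interfaces: int, n_partners: int) -> str:
    """Structural hub class: >=5 partners, then <=2 interfaces SIH else MIH."""
    if n_mutually_exclusive_interfaces < 0 or n_partners < 0:
        raise ValueError("counts must be non-negative")
    if n_partners < 5:
        return "not_hub"
    return "SIH" if n_mutually_exclusive_interfaces <= 2 else "MIH"


def label_kinetic_class(mean_pcc: float, n_partners: int) -> str:
    """Kinetic hub class: >=5 partners, then PCC <= 0.5 date else party."""
    if not (-1.0 <= mean_pcc <= 1.0):
        raise ValueError(f"mean_pcc out of [-1, 1]: {mean_pcc}")
    if n_partners < 0:
        raise ValueError("partner count must be non-negative")
    if n_partners < 5:
        return "not_hub"
    return "date" if mean_pcc <= 0.5 else "party"
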