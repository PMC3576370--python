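"""Ranked homology search and hit-based decision rules.

Two interchangeable backends produce ranked hit lists:

* :class:`SmithWatermanBackend` (default) — deterministic local alignment
  (BLOSUM62, gap open 11 / extend 1) with e-values from the Karlin-Altschul
  formula using fixed gapped-BLOSUM62 parameters.  No external binary needed.
* :class:`BlastBackend` — shells out to NCBI BLAST+ (``psiblast``), parsing
  standard tabular output (outfmt 6).

On top of the hit lists sit three annotation-transfer rules: binary
classification by the single top-scoring hit (the homology attribute of the
stacked ensemble), hub-status calling from the top four hits, and a
bit-score-weighted estimate of the number of interaction partners.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import LabeledDataset, ProteinRecord, write_fasta

# Karlin-Altschul parameters for gapped BLOSUM62 (gap 11/1); fixed by design.
KA_LAMBDA = 0.267
KA_K = 0.041
LN2 = math.log(2.0)

DEFAULT_E_CUTOFF = 1e-4


class BackendError(RuntimeError):
    """Raised when a search backend fails; carries backend diagnostics."""


@dataclass(frozen=True)
class HomologyHit:
    subject_id: str
    e_value: float
    bit_score: float
    subject_class: str | None = None
    subject_interactors: int | None = None


@dataclass
class HomologyHitList:
    """Hits for one query, sorted by (e-value asc, bit score desc, id)."""

    query_id: str
    hits: list[HomologyHit]

    def top(self, n: int) -> list[HomologyHit]:
        return self.hits[:n]


@dataclass
class SearchConfig:
    e_cutoff: float = DEFAULT_E_CUTOFF
    weight_scheme: str = "bit_score"  # or "neg_log_evalue"
    max_hits: int | None = None


def _sort_hits(hits: list[HomologyHit]) -> list[HomologyHit]:
    return sorted(hits, key=lambda h: (h.e_value, -h.bit_score, h.subject_id))


def raw_to_bit(raw_score: float) -> float:
    """Karlin-Altschul normalised (bit) score from a raw alignment score."""
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / LN2


def bit_to_evalue(bit_score: float, query_len: int, db_residues: int) -> float:
    """Expected chance hits in a search space of query_len x db_residues."""
    return query_len * db_residues * 2.0 ** (-bit_score)


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


class SmithWatermanBackend:
    """Built-in all-vs-reference scorer with a raw-score cache.

    Alignment scores depend only on the two residue strings, so they are
    cached across searches (e.g. across cross-validation folds and label
    permutations over the same sequences).
    """

    def __init__(self) -> None:
        self._aligner = make_aligner()
        self._cache: dict[tuple[str, str], float] = {}

    def raw_score(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        score = self._cache.get(key)
        if score is None:
            score = float(self._aligner.score(a, b))
            self._cache[key] = score
        return score

    def search_many(
        self,
        queries: Sequence[ProteinRecord],
        reference: Sequence[ProteinRecord],
        e_cutoff: float,
    ) -> dict[str, list[tuple[str, float, float]]]:
        """Per-query list of (subject_id, bit_score, e_value) passing cutoff."""
        db_residues = sum(r.length for r in reference)
        out: dict[str, list[tuple[str, float, float]]] = {}
        for q in queries:
            rows = []
            for s in reference:
                if s.id == q.id:
                    continue
                bit = raw_to_bit(self.raw_score(q.residues, s.residues))
                ev = bit_to_evalue(bit, q.length, db_residues)
                if ev <= e_cutoff:
                    rows.append((s.id, bit, ev))
            out[q.id] = rows
        return out


class BlastBackend:
    """External NCBI BLAST+ backend (PSI-BLAST semantics, tabular output)."""

    def __init__(self, program: str = "psiblast", makeblastdb: str = "makeblastdb"):
        self.program = program
        self.makeblastdb = makeblastdb

    def available(self) -> bool:
        return shutil.which(self.program) is not None and shutil.which(self.makeblastdb) is not None

    def search_many(
        self,
        queries: Sequence[ProteinRecord],
        reference: Sequence[ProteinRecord],
        e_cutoff: float,
    ) -> dict[str, list[tuple[str, float, float]]]:
        if not self.available():
            raise BackendError(f"{self.program} / {self.makeblastdb} not found on PATH")
        with tempfile.TemporaryDirectory(prefix="hubseq_blast_") as tmp:
            tmp = Path(tmp)
            db_fa, q_fa, out_tab = tmp / "db.fasta", tmp / "q.fasta", tmp / "hits.tsv"
            write_fasta(reference, db_fa)
            write_fasta(queries, q_fa)
            try:
                subprocess.run(
                    [self.makeblastdb, "-in", str(db_fa), "-dbtype", "prot"],
                    check=True, capture_output=True, text=True,
                )
                subprocess.run(
                    [
                        self.program, "-query", str(q_fa), "-db", str(db_fa),
                        "-evalue", str(e_cutoff), "-outfmt", "6", "-out", str(out_tab),
                    ],
                    check=True, capture_output=True, text=True,
                )
            except subprocess.CalledProcessError as exc:
                raise BackendError(f"BLAST backend failed: {exc.stderr}") from exc
            raw = parse_blast_tabular(out_tab.read_text())
        out: dict[str, list[tuple[str, float, float]]] = {q.id: [] for q in queries}
        for qid, sid, ev, bit in raw:
            if qid in out and sid != qid and ev <= e_cutoff:
                out[qid].append((sid, bit, ev))
        return out


def parse_blast_tabular(text: str) -> list[tuple[str, str, float, float]]:
    """Parse BLAST outfmt 6 rows into (query, subject, e_value, bit_score).

    Keeps only the best row per (query, subject) pair.
    """
    best: dict[tuple[str, str], tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise BackendError(f"malformed tabular line: {line!r}")
        qid, sid, ev, bit = fields[0], fields[1], float(fields[10]), float(fields[11])
        key = (qid, sid)
        if key not in best or (ev, -bit) < (best[key][0], -best[key][1]):
            best[key] = (ev, bit)
    return [(q, s, ev, bit) for (q, s), (ev, bit) in best.items()]


_DEFAULT_BACKEND: SmithWatermanBackend | None = None


def default_backend() -> SmithWatermanBackend:
    """Module-level built-in backend (shared alignment-score cache)."""
    global _DEFAULT_BACKEND
    if _DEFAULT_BACKEND is None:
        _DEFAULT_BACKEND = SmithWatermanBackend()
    return _DEFAULT_BACKEND


def _annotate(
    qid: str,
    rows: list[tuple[str, float, float]],
    reference: LabeledDataset,
    max_hits: int | None,
) -> HomologyHitList:
    hits = []
    for sid, bit, ev in rows:
        cls = str(reference.labels.get(sid, reference.class_field))
        inter = reference.labels.get(sid, "interactor_count")
        hits.append(
            HomologyHit(
                subject_id=sid, e_value=ev, bit_score=bit,
                subject_class=cls, subject_interactors=inter,
            )
        )
    hits = _sort_hits(hits)
    if max_hits is not None:
        hits = hits[:max_hits]
    return HomologyHitList(query_id=qid, hits=hits)


def search(
    query: ProteinRecord,
    reference: LabeledDataset,
    config: SearchConfig | None = None,
    backend=None,
) -> HomologyHitList:
    """Search one query against a labelled reference database."""
    return search_many([query], reference, config, backend)[query.id]


def search_many(
    queries: Sequence[ProteinRecord],
    reference: LabeledDataset,
    config: SearchConfig | None = None,
    backend=None,
) -> dict[str, HomologyHitList]:
    """Batch search; hits are filtered at the e-value cutoff, self-hits
    excluded, and re-sorted by the deterministic total order."""
    config = config or SearchConfig()
    backend = backend or default_backend()
    if not reference.records:
        raise ValueError("reference database is empty")
    raw = backend.search_many(queries, reference.records, config.e_cutoff)
    return {
        q.id: _annotate(q.id, raw[q.id], reference, config.max_hits) for q in queries
    }


# ---------------------------------------------------------------------------
# Decision rules
# ---------------------------------------------------------------------------


def classify_by_top_hit(hits: HomologyHitList, target_class: str) -> int:
    """1 iff the top-scoring hit carries ``target_class``; else (or with no
    hits) 0."""
    if not hits.hits:
        return 0
    return int(hits.hits[0].subject_class == target_class)


@dataclass
class HubCall:
    """Hub-status call plus interactor-count summaries from the top hits."""

    status: str  # hub | likely_hub | non_hub | likely_non_hub | unknown
    top_hit_interactors: int | None = None
    interactor_range: tuple[int, int] | None = None
    weighted_estimate: float | None = None


_LIKELY = {"hub": "likely_hub", "non_hub": "likely_non_hub"}


def call_hub_status(hits: HomologyHitList, config: SearchConfig | None = None) -> HubCall:
    """Call hub / non-hub status from the top four hits.

    Four hits: unanimous agreement gives the definite status; a 3-of-4
    majority gives the 'likely' status; a 2-2 split is unknown.  With one to
    three hits only a unanimous 'likely' call is made.  No hits: unknown.
    """
    top = hits.top(4)
    classes = [h.subject_class for h in top]
    if any(c not in ("hub", "non_hub") for c in classes):
        raise ValueError("call_hub_status requires hub/non_hub subject classes")
    if not top:
        return HubCall(status="unknown")
    n_hub = classes.count("hub")
    if len(top) == 4:
        if n_hub == 4:
            status = "hub"
        elif n_hub == 0:
            status = "non_hub"
        elif n_hub == 3:
            status = "likely_hub"
        elif n_hub == 1:
            status = "likely_non_hub"
        else:
            status = "unknown"
    else:  # 1-3 hits: unanimity yields at most a 'likely' call
        if n_hub == len(top):
            status = "likely_hub"
        elif n_hub == 0:
            status = "likely_non_hub"
        else:
            status = "unknown"
    top_count, rng, est = estimate_interactors(hits, config)
    return HubCall(
        status=status,
        top_hit_interactors=top_count,
        interactor_range=rng,
        weighted_estimate=est,
    )


def _weight(hit: HomologyHit, scheme: str) -> float:
    if scheme == "bit_score":
        return hit.bit_score
    if scheme == "neg_log_evalue":
        # floor avoids zero/negative weights for weak hits near the cutoff
        return max(-math.log10(hit.e_value), 1e-9)
    raise ValueError(f"unknown weight scheme {scheme!r}")


def estimate_interactors(
    hits: HomologyHitList, config: SearchConfig | None = None
) -> tuple[int | None, tuple[int, int] | None, float | None]:
    """Interactor-count summaries over the top four hits.

    Returns (top-hit count, (min, max) range, score-weighted mean); the
    weighted mean uses bit scores by default and is invariant to uniform
    weight scaling.  Hits without interactor data are excluded; if none has
    data, all three values are unset.
    """
    config = config or SearchConfig()
    top = [h for h in hits.top(4) if h.subject_interactors is not None]
    if not top:
        return None, None, None
    top_count = (
        hits.hits[0].subject_interactors if hits.hits else None
    )
    counts = [h.subject_interactors for h in top]
    weights = [_weight(h, config.weight_scheme) for h in top]
    est = sum(w * n for w, n in zip(weights, counts)) / sum(weights)
    return top_count, (min(counts), max(counts)), est


class HomologyClassifierSpec:
    """Cross-validation adapter: classify by the top hit against the
    training folds (the reference database never contains the query fold)."""

    def __init__(self, positive_class: str, config: SearchConfig | None = None, backend=None):
        self.positive_class = positive_class
        self.config = config or SearchConfig()
        self.backend = backend

    def fit(self, train: LabeledDataset):
        return train  # the reference database *is* the model

    def predict(self, fitted: LabeledDataset, records, reference=None):
        lists = search_many(records, fitted, self.config, self.backend)
        neg = [c for c in fitted.classes if c != self.positive_class][0]
        labels, scores = [], []
        for rec in records:
            bit = classify_by_top_hit(lists[rec.id], self.positive_class)
            labels.append(self.positive_class if bit else neg)
            scores.append(float(bit))
        return labels, scores
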