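"""Three-phase orchestration.

Phase I decides protein-binding (PB) vs non-protein-binding (NPB) with a
HybSVM model.  Proteins called NPB stop there.  PB proteins proceed to
Phase II, a homology-based hub call against a reference database labelled
with hub status and interactor counts, and to Phase III, two further HybSVM
models for the structural (SIH vs MIH) and kinetic (date vs party) hub
classes.  By default Phase III runs on every PB protein regardless of the
Phase II call; a config flag restricts it to confirmed/likely hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from . import homology as hom
from .ensemble import HybSVMModel, predict_hybsvm_many
from .sequence_io import NA_TOKEN, LabeledDataset, ProteinRecord

logger = logging.getLogger("hubseq.pipeline")


@dataclass
class PipelineConfig:
    search: hom.SearchConfig = field(default_factory=hom.SearchConfig)
    #: run Phase III only for proteins Phase II calls hub / likely_hub
    phase3_hubs_only: bool = False


@dataclass
class PredictionRecord:
    """Per-protein three-phase output.

    Phase II/III fields are set only when Phase I predicts PB; probabilities
    of the predicted class lie in [0.5, 1].
    """

    id: str
    phase1_label: str
    phase1_score: float
    phase2: hom.HubCall | None = None
    phase3_interface: tuple[str, float] | None = None
    phase3_kinetic: tuple[str, float] | None = None

    def as_row(self) -> tuple:
        hub = self.phase2
        rng = hub.interactor_range if hub else None
        return (
            self.id,
            self.phase1_label,
            self.phase1_score,
            hub.status if hub else None,
            hub.top_hit_interactors if hub else None,
            rng[0] if rng else None,
            rng[1] if rng else None,
            hub.weighted_estimate if hub else None,
            self.phase3_interface[0] if self.phase3_interface else None,
            self.phase3_interface[1] if self.phase3_interface else None,
            self.phase3_kinetic[0] if self.phase3_kinetic else None,
            self.phase3_kinetic[1] if self.phase3_kinetic else None,
        )

    @classmethod
    def from_row(cls, row: Sequence[str]) -> "PredictionRecord":
        def opt(v):
            return None if v == NA_TOKEN else v

        (ident, p1l, p1s, status, top, lo, hi, est, p3il, p3is, p3kl, p3ks) = row
        phase2 = None
        if opt(status) is not None:
            phase2 = hom.HubCall(
                status=status,
                top_hit_interactors=int(top) if opt(top) is not None else None,
                interactor_range=(
                    (int(lo), int(hi)) if opt(lo) is not None and opt(hi) is not None else None
                ),
                weighted_estimate=float(est) if opt(est) is not None else None,
            )
        return cls(
            id=ident,
            phase1_label=p1l,
            phase1_score=float(p1s),
            phase2=phase2,
            phase3_interface=(p3il, float(p3is)) if opt(p3il) is not None else None,
            phase3_kinetic=(p3kl, float(p3ks)) if opt(p3kl) is not None else None,
        )


def run_three_phase(
    queries: Sequence[ProteinRecord],
    phase1_model: HybSVMModel,
    phase2_reference: LabeledDataset,
    phase3_interface_model: HybSVMModel,
    phase3_kinetic_model: HybSVMModel,
    config: PipelineConfig | None = None,
    backend=None,
) -> list[PredictionRecord]:
    """Classify queries through all three phases; one output per query."""
    config = config or PipelineConfig()
    for name, model in (
        ("phase1", phase1_model),
        ("phase3_interface", phase3_interface_model),
        ("phase3_kinetic", phase3_kinetic_model),
    ):
        if model is None:
            raise ValueError(f"missing model for {name}")
    if not queries:
        return []
    logger.info("phase I: classifying %d queries", len(queries))
    phase1 = predict_hybsvm_many(phase1_model, queries, backend=backend)
    pb_records = [
        q for q, (label, _, _) in zip(queries, phase1)
        if label == phase1_model.target_class
    ]
    logger.info("phase I: %d predicted PB / %d", len(pb_records), len(queries))

    hub_calls: dict[str, hom.HubCall] = {}
    if pb_records:
        hit_lists = hom.search_many(pb_records, phase2_reference, config.search, backend)
        for rec in pb_records:
            hub_calls[rec.id] = hom.call_hub_status(hit_lists[rec.id], config.search)
    logger.info("phase II: %d hub calls", len(hub_calls))

    if config.phase3_hubs_only:
        phase3_records = [
            q for q in pb_records
            if hub_calls[q.id].status in ("hub", "likely_hub")
        ]
    else:
        phase3_records = pb_records
    interface_preds: dict[str, tuple[str, float]] = {}
    kinetic_preds: dict[str, tuple[str, float]] = {}
    if phase3_records:
        for rec, row in zip(
            phase3_records,
            predict_hybsvm_many(phase3_interface_model, phase3_records, backend=backend),
        ):
            interface_preds[rec.id] = (row[0], row[1])
        for rec, row in zip(
            phase3_records,
            predict_hybsvm_many(phase3_kinetic_model, phase3_records, backend=backend),
        ):
            kinetic_preds[rec.id] = (row[0], row[1])
    logger.info("phase III: %d classified", len(phase3_records))

    out = []
    for q, (label, prob, _) in zip(queries, phase1):
        out.append(
            PredictionRecord(
                id=q.id,
                phase1_label=label,
                phase1_score=prob,
                phase2=hub_calls.get(q.id),
                phase3_interface=interface_preds.get(q.id),
                phase3_kinetic=kinetic_preds.get(q.id),
            )
        )
    return out


_PHASE_SCORE = {
    "phase1": lambda r: r.phase1_score,
    "phase3_interface": lambda r: r.phase3_interface[1] if r.phase3_interface else None,
    "phase3_kinetic": lambda r: r.phase3_kinetic[1] if r.phase3_kinetic else None,
}


def filter_by_score(
    records: Sequence[PredictionRecord],
    min_probability: float,
    phase: str = "phase1",
) -> tuple[list[PredictionRecord], float]:
    """Keep records whose probability for the given phase clears the
    threshold; also report the retained coverage fraction.

    Trading coverage for reliability this way mirrors how score cutoffs of
    0.70 or 0.90 shrink the prediction set while raising its accuracy.
    """
    if phase not in _PHASE_SCORE:
        raise ValueError(f"unknown phase {phase!r}")
    score = _PHASE_SCORE[phase]
    kept = [r for r in records if score(r) is not None and score(r) >= min_probability]
    coverage = len(kept) / len(records) if records else 0.0
    return kept, coverage
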