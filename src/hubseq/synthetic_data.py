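"""Synthetic corpora with the statistical structure the classifiers assume.

Class-conditional sequence composition is emulated with per-class Markov
emitters (order 0 or 1) whose transition rows are drawn from a Dirichlet;
lower concentration gives larger total-variation separation between the
class emitters.  Homologous families are produced by i.i.d. substitution at
a controlled identity.  Label fields (interactor counts, interface counts,
mean co-expression PCC, domain counts) are drawn per hub tier so every
labelling threshold downstream is exercised.

Everything is driven by one integer seed; outputs are byte-identical across
runs with the same spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import nbinom

from .sequence_io import (
    AMINO_ACIDS,
    LabelTable,
    LabeledDataset,
    ProteinRecord,
    write_fasta,
    write_labels,
)

_A = len(AMINO_ACIDS)
_IDX = {c: i for i, c in enumerate(AMINO_ACIDS)}


@dataclass
class MarkovEmitter:
    """Order-0 (i.i.d.) or order-1 Markov sequence emitter."""

    order: int
    initial: np.ndarray  # (20,)
    transition: np.ndarray | None = None  # (20, 20) for order 1

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise ValueError("emitter order must be 0 or 1")
        if self.order == 1 and self.transition is None:
            raise ValueError("order-1 emitter needs a transition matrix")

    def emit(self, length: int, rng: np.random.Generator) -> str:
        if length <= 0:
            raise ValueError("length must be positive")
        if self.order == 0:
            idx = rng.choice(_A, size=length, p=self.initial)
            return "".join(AMINO_ACIDS[i] for i in idx)
        cum = np.cumsum(self.transition, axis=1)
        cum[:, -1] = 1.0
        out = np.empty(length, dtype=np.int64)
        out[0] = rng.choice(_A, p=self.initial)
        u = rng.random(length - 1)
        for i in range(1, length):
            out[i] = int(np.searchsorted(cum[out[i - 1]], u[i - 1], side="right"))
        return "".join(AMINO_ACIDS[i] for i in out)

    def stationary(self) -> np.ndarray:
        """Stationary letter distribution of the chain."""
        if self.order == 0:
            return self.initial
        vals, vecs = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, i])
        v = np.abs(v)
        return v / v.sum()


def emitter_separation(a: MarkovEmitter, b: MarkovEmitter) -> float:
    """Mean total-variation distance between corresponding emitter rows."""
    if a.order != b.order:
        raise ValueError("emitters must share an order")
    if a.order == 0:
        return 0.5 * float(np.abs(a.initial - b.initial).sum())
    return 0.5 * float(np.abs(a.transition - b.transition).sum(axis=1).mean())


@dataclass
class ClassPlan:
    """What to emit and how to label one synthetic class."""

    name: str
    n: int
    binding_class: str | None = None  # "PB" / "NPB"
    hub_tier: str | None = None  # "hub" | "excluded" | "non_hub"
    interface_class: str | None = None  # "SIH" / "MIH"
    kinetic_class: str | None = None  # "date" / "party"
    domain_profile: dict[str, float] | None = None  # domain -> Poisson mean
    family_size: int = 1  # >1: sequences come in homolog families
    family_identity: float = 0.9


@dataclass
class GeneratorTemplate:
    """Free parameters of a corpus; emitters are drawn by sample_generator."""

    classes: list[ClassPlan]
    length: int = 300
    order: int = 1
    concentration: float = 0.1
    hub_convention: str = "banded"  # "banded" (>5/<3) or "ge5"


@dataclass
class GeneratorSpec:
    """A template with concrete emitter parameters and a mandatory seed."""

    template: GeneratorTemplate
    emitters: dict[str, MarkovEmitter]
    separation: float
    seed: int

    @property
    def classes(self) -> list[ClassPlan]:
        return self.template.classes


def _draw_emitter(order: int, concentration: float, rng: np.random.Generator) -> MarkovEmitter:
    alpha = np.full(_A, concentration)
    initial = rng.dirichlet(alpha)
    if order == 0:
        return MarkovEmitter(order=0, initial=initial)
    transition = np.vstack([rng.dirichlet(alpha) for _ in range(_A)])
    return MarkovEmitter(order=1, initial=initial, transition=transition)


def sample_generator(template: GeneratorTemplate, seed: int) -> GeneratorSpec:
    """Draw concrete emitter parameters for every class in the template.

    The achieved separation reported is the minimum pairwise separation over
    all class pairs (equal to the pairwise separation for two classes).
    """
    rng = np.random.default_rng(seed)
    emitters = {
        plan.name: _draw_emitter(template.order, template.concentration, rng)
        for plan in template.classes
    }
    names = list(emitters)
    seps = [
        emitter_separation(emitters[a], emitters[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    ]
    return GeneratorSpec(
        template=template,
        emitters=emitters,
        separation=min(seps) if seps else 0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Label-field samplers
# ---------------------------------------------------------------------------

# Interactor counts per hub tier: shifted negative binomials, truncated to
# the tier's band where the band is bounded.
_TIER_BANDS = {
    "banded": {"non_hub": (0, 2), "excluded": (3, 5), "hub": (6, None)},
    "ge5": {"non_hub": (0, 2), "excluded": (3, 4), "hub": (5, None)},
}
_NB_R, _NB_P = 3, 0.35  # dispersion of the hub-tail count distribution


def _sample_interactors(tier: str, convention: str, rng: np.random.Generator) -> int:
    lo, hi = _TIER_BANDS[convention][tier]
    if hi is None:
        return lo + int(rng.negative_binomial(_NB_R, _NB_P))
    support = np.arange(lo, hi + 1)
    w = nbinom.pmf(support, _NB_R, _NB_P) + 1e-12
    return int(rng.choice(support, p=w / w.sum()))


def _sample_pcc(kinetic: str, rng: np.random.Generator) -> float:
    if kinetic == "date":
        return float(rng.uniform(-0.2, 0.5))
    if kinetic == "party":
        return float(rng.uniform(0.55, 0.95))
    raise ValueError(f"unknown kinetic class {kinetic!r}")


def _sample_interfaces(interface: str, rng: np.random.Generator) -> int:
    if interface == "SIH":
        return int(rng.integers(1, 3))  # 1 or 2
    if interface == "MIH":
        return 3 + int(rng.negative_binomial(2, 0.5))
    raise ValueError(f"unknown interface class {interface!r}")


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


def mutate_family(
    seed_record: ProteinRecord,
    target_identity: float,
    family_size: int,
    seed: int | np.random.Generator,
) -> list[ProteinRecord]:
    """Homologs of a seed by i.i.d. substitutions at rate 1 - target_identity.

    Each substituted position receives a uniformly random *different*
    residue, so the expected pointwise identity to the seed equals the
    target.
    """
    if not (0.0 <= target_identity <= 1.0):
        raise ValueError("target_identity must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    base = np.array([_IDX[c] for c in seed_record.residues])
    for j in range(family_size):
        mutate = rng.random(len(base)) < (1.0 - target_identity)
        mutated = base.copy()
        if mutate.any():
            shifts = rng.integers(1, _A, size=int(mutate.sum()))
            mutated[mutate] = (mutated[mutate] + shifts) % _A
        out.append(
            ProteinRecord(
                id=f"{seed_record.id}_hom{j}",
                residues="".join(AMINO_ACIDS[i] for i in mutated),
            )
        )
    return out


def generate_corpus(
    spec: GeneratorSpec,
    fasta_path=None,
    labels_path=None,
) -> tuple[list[ProteinRecord], LabelTable]:
    """Emit sequences and a fully populated label table for every class.

    When ``family_size > 1`` for a class, sequences come in homolog families:
    family seeds are emitted from the class emitter and members derived by
    substitution at the plan's family identity.  Label fields are sampled
    per record from the plan's tiers.  If paths are given, the FASTA and
    label TSV are written (byte-identical across runs for a fixed spec).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    rows: list[dict] = []
    length = spec.template.length
    convention = spec.template.hub_convention
    for plan in spec.classes:
        emitter = spec.emitters[plan.name]
        seqs: list[ProteinRecord] = []
        if plan.family_size > 1:
            n_seeds = -(-plan.n // plan.family_size)
            for s in range(n_seeds):
                seed_rec = ProteinRecord(
                    id=f"{plan.name}_f{s:03d}", residues=emitter.emit(length, rng)
                )
                seqs.extend(
                    mutate_family(seed_rec, plan.family_identity, plan.family_size, rng)
                )
            seqs = seqs[: plan.n]
        else:
            seqs = [
                ProteinRecord(id=f"{plan.name}_{i:04d}", residues=emitter.emit(length, rng))
                for i in range(plan.n)
            ]
        for rec in seqs:
            row: dict[str, object] = {"id": rec.id, "class_name": plan.name}
            if plan.binding_class is not None:
                row["binding_class"] = plan.binding_class
            if plan.hub_tier is not None:
                row["interactor_count"] = _sample_interactors(plan.hub_tier, convention, rng)
                if plan.hub_tier in ("hub", "non_hub"):
                    row["hub_status"] = plan.hub_tier
            if plan.interface_class is not None:
                row["interface_class"] = plan.interface_class
                row["interface_count"] = _sample_interfaces(plan.interface_class, rng)
            if plan.kinetic_class is not None:
                row["kinetic_class"] = plan.kinetic_class
                row["mean_pcc"] = round(_sample_pcc(plan.kinetic_class, rng), 6)
            if plan.domain_profile is not None:
                counts = {
                    dom: int(rng.poisson(mean)) for dom, mean in sorted(plan.domain_profile.items())
                }
                row["domain_counts"] = {d: n for d, n in counts.items() if n > 0}
            rows.append(row)
        records.extend(seqs)
    labels = LabelTable.from_records(rows)
    if fasta_path is not None:
        write_fasta(records, fasta_path)
    if labels_path is not None:
        write_labels(labels, labels_path)
    return records, labels


def complementary_corpus(
    seed: int,
    n_comp: int = 40,
    n_fam: int = 40,
    length: int = 100,
    family_size: int = 4,
    family_identity: float = 0.95,
    ancestor_identity: float = 0.93,
) -> LabeledDataset:
    """Two-class corpus whose signal is split between composition and homology.

    Half of each class (the *composition* subset) is emitted from
    class-specific order-1 emitters with near-uniform letter frequencies
    (Dirichlet concentration 5), so the k-gram classifiers separate it but
    pairwise alignments stay insignificant.  The other half (the *family*
    subset) is built from paralog pairs: each family derives a pos- and a
    neg-subfamily from one common ancestor (itself emitted by a shared
    high-entropy emitter), so family-level composition quirks are shared
    across the class boundary and carry no class signal, while the nearest
    alignment hit stays inside the correct subfamily (within-subfamily
    identity ~``family_identity`` vs ~``ancestor_identity``^2 across).  The
    k-gram components and the homology component therefore err on
    complementary subsets.
    """
    rng = np.random.default_rng(seed)
    comp_emitters = {
        "pos": _draw_emitter(1, 5.0, rng),
        "neg": _draw_emitter(1, 5.0, rng),
    }
    fam_emitter = _draw_emitter(0, 50.0, rng)
    records: list[ProteinRecord] = []
    rows: list[dict] = []
    for cls in ("pos", "neg"):
        for i in range(n_comp):
            rec = ProteinRecord(
                id=f"{cls}_c{i:03d}", residues=comp_emitters[cls].emit(length, rng)
            )
            records.append(rec)
            rows.append({"id": rec.id, "class_name": cls})
    n_families = -(-n_fam // family_size)
    fam_members: dict[str, list[ProteinRecord]] = {"pos": [], "neg": []}
    for f in range(n_families):
        ancestor = ProteinRecord(id=f"anc_{f:02d}", residues=fam_emitter.emit(length, rng))
        for cls in ("pos", "neg"):
            subfamily_seed = mutate_family(ancestor, ancestor_identity, 1, rng)[0]
            subfamily_seed = ProteinRecord(
                id=f"{cls}_f{f:02d}", residues=subfamily_seed.residues
            )
            fam_members[cls].extend(
                mutate_family(subfamily_seed, family_identity, family_size, rng)
            )
    for cls in ("pos", "neg"):
        for rec in fam_members[cls][:n_fam]:
            records.append(rec)
            rows.append({"id": rec.id, "class_name": cls})
    return LabeledDataset(
        records=records, labels=LabelTable.from_records(rows), class_field="class_name"
    )


def homology_only_corpus(
    seed: int,
    n_per_class: int = 200,
    length: int = 100,
    family_size: int = 4,
    family_identity: float = 0.95,
) -> LabeledDataset:
    """Two-class corpus where only homology carries signal.

    Every sequence descends from one shared high-entropy emitter, so the
    class-conditional composition is identical; class membership follows
    homolog families.  The seven k-gram components are uninformative while
    the top-hit homology transfer is essentially perfect.
    """
    rng = np.random.default_rng(seed)
    emitter = _draw_emitter(0, 50.0, rng)
    records: list[ProteinRecord] = []
    rows: list[dict] = []
    for cls in ("pos", "neg"):
        members: list[ProteinRecord] = []
        n_seeds = -(-n_per_class // family_size)
        for s in range(n_seeds):
            seed_rec = ProteinRecord(
                id=f"{cls}_f{s:03d}", residues=emitter.emit(length, rng)
            )
            members.extend(mutate_family(seed_rec, family_identity, family_size, rng))
        for rec in members[:n_per_class]:
            records.append(rec)
            rows.append({"id": rec.id, "class_name": cls})
    return LabeledDataset(
        records=records, labels=LabelTable.from_records(rows), class_field="class_name"
    )


def permute_class_labels(data: LabeledDataset, seed: int) -> LabeledDataset:
    """Copy of a dataset with its class column randomly permuted."""
    rng = np.random.default_rng(seed)
    ids = [r.id for r in data.records]
    values = [data.class_of(i) for i in ids]
    perm = rng.permutation(len(values))
    labels = data.labels.with_column(
        data.class_field, {ident: values[j] for ident, j in zip(ids, perm)}
    )
    return LabeledDataset(
        records=data.records, labels=labels, class_field=data.class_field
    )


def binary_corpus(
    n_per_class: int,
    length: int,
    seed: int,
    *,
    concentration: float = 0.1,
    order: int = 1,
    class_field: str = "class_name",
    names: tuple[str, str] = ("alpha", "beta"),
    min_separation: float | None = None,
    family_size: int = 1,
    family_identity: float = 0.9,
) -> tuple[LabeledDataset, GeneratorSpec]:
    """Two-class corpus ready for classifier training.

    With ``min_separation`` set, emitter draws are repeated (with a seed
    offset) until the achieved separation clears the floor; the draw is
    deterministic given the seed.
    """
    template = GeneratorTemplate(
        classes=[
            ClassPlan(name=names[0], n=n_per_class, family_size=family_size,
                      family_identity=family_identity),
            ClassPlan(name=names[1], n=n_per_class, family_size=family_size,
                      family_identity=family_identity),
        ],
        length=length,
        order=order,
        concentration=concentration,
    )
    draw_seed = seed
    spec = sample_generator(template, draw_seed)
    while min_separation is not None and spec.separation < min_separation:
        draw_seed += 1
        spec = sample_generator(template, draw_seed)
    records, labels = generate_corpus(replace(spec, seed=seed))
    return LabeledDataset(records=records, labels=labels, class_field=class_field), spec
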