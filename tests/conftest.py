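import pytest

from hubseq.sequence_io import LabelTable, LabeledDataset, ProteinRecord
from hubseq.synthetic_data import binary_corpus


def make_dataset(seq_by_class: dict[str, list[str]], class_field: str = "cls") -> LabeledDataset:
    """Tiny labelled dataset from {class: [residue strings]}."""
    records, rows = [], []
    for cls, seqs in seq_by_class.items():
        for i, s in enumerate(seqs):
            rec = ProteinRecord(id=f"{cls}{i}", residues=s)
            records.append(rec)
            rows.append({"id": rec.id, class_field: cls})
    return LabeledDataset(
        records=records,
        labels=LabelTable.from_records(rows),
        class_field=class_field,
        binary=len(seq_by_class) == 2,
    )


@pytest.fixture(scope="session")
def separated_corpus():
    """Two well-separated order-1 classes (40/class, length 150)."""
    ds, spec = binary_corpus(40, 150, seed=91, concentration=0.1, min_separation=0.3)
    return ds, spec
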