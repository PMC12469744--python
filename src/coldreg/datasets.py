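"""Training/validation/test assembly with gene-family disjointness.

Genes from the same family share ancestry and hence sequence, so a random
per-record split would leak training information into the test set. The
split unit here is therefore the gene family: families are shuffled and
accumulated greedily until the target record fraction is reached, first
for the test set, then for the validation set out of the remaining
training families. Oversampling (minority class resampled with
replacement to 1:1) is applied to the training partition only; validation
and test retain the original ~1:11 class ratio.

Binary labels follow the convention DEG = 0, non-DEG = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import DEGLabel, GeneAnnotation
from .regions import RegulatoryInput, build_input

DEG_CLASS = 0
NON_CLASS = 1


class SplitError(ValueError):
    pass


class ImbalanceError(ValueError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.20
    validation_fraction_of_train: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("test_fraction", "validation_fraction_of_train"):
            f = getattr(self, name)
            if not (0 < f < 1):
                raise ValueError(f"{name} must be in (0, 1), got {f}")


@dataclass
class LabeledSet:
    """A list of labelled records plus cached dense arrays for training."""

    records: list[RegulatoryInput]
    _X: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def class_counts(self) -> dict[int, int]:
        counts = {DEG_CLASS: 0, NON_CLASS: 0}
        for r in self.records:
            counts[r.label] += 1
        return counts

    @property
    def y(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int8)

    @property
    def X(self) -> np.ndarray:
        """(N, L, 4) float32 stack of the records' one-hot encodings."""
        if self._X is None:
            self._X = np.stack([r.onehot for r in self.records]).astype(np.float32)
        return self._X

    def __len__(self) -> int:
        return len(self.records)


def binary_label(status: str, contrast: str) -> int | None:
    """Map a status to the binary target for the given contrast ("up"/"down").

    The opposite DEG class is excluded (returns None): the up-contrast is
    up-regulated DEGs vs non-DEGs, with down-regulated genes left out.
    """
    if contrast not in ("up", "down"):
        raise ValueError(f"contrast must be 'up' or 'down', got {contrast!r}")
    if status == contrast:
        return DEG_CLASS
    if status == "non":
        return NON_CLASS
    return None


def build_records(
    annotations: list[GeneAnnotation],
    genomes: dict[str, dict[str, str]],
    labels: list[DEGLabel],
    contrast: str = "up",
    mode: str = "both_regions",
) -> list[RegulatoryInput]:
    """One record per (gene, accession) pair for the chosen contrast.

    The same gene appears once per accession, with the window extracted
    from that accession's genome.
    """
    by_gene = {a.gene_id: a for a in annotations}
    out: list[RegulatoryInput] = []
    for lab in labels:
        y = binary_label(lab.status, contrast)
        if y is None:
            continue
        gene = by_gene[lab.gene_id]
        out.append(build_input(gene, lab.accession_id, genomes[lab.accession_id], mode, label=y))
    return out


def split_by_family(
    records: list[RegulatoryInput], spec: SplitSpec
) -> tuple[LabeledSet, LabeledSet, LabeledSet]:
    """Family-disjoint (train, validation, test) partitions.

    Greedy accumulation of shuffled families until the target record
    fraction is reached; deterministic per seed. No family appears in more
    than one partition.
    """
    families: dict[str, list[RegulatoryInput]] = {}
    for r in records:
        families.setdefault(r.family_id, []).append(r)
    if len(families) < 3:
        raise SplitError(f"need at least 3 gene families to split, got {len(families)}")
    rng = np.random.default_rng(spec.seed)
    order = sorted(families)
    rng.shuffle(order)
    total = len(records)

    test_fams = _take_until(order, families, spec.test_fraction * total)
    remaining = [f for f in order if f not in test_fams]
    n_remaining = sum(len(families[f]) for f in remaining)
    val_fams = _take_until(
        remaining, families, spec.validation_fraction_of_train * n_remaining
    )
    train_fams = [f for f in remaining if f not in val_fams]
    if not train_fams:
        raise SplitError("split left no families for training; lower the fractions")

    def collect(fams):
        return LabeledSet([r for f in fams for r in families[f]])

    return collect(train_fams), collect(val_fams), collect(test_fams)


def _take_until(order: list[str], families: dict, target: float) -> set[str]:
    taken: set[str] = set()
    count = 0
    for fam in order:
        if count >= target:
            break
        taken.add(fam)
        count += len(families[fam])
    return taken


def oversample(train: LabeledSet, seed: int = 0) -> LabeledSet:
    """Resample the minority class with replacement to a 1:1 ratio.

    Only ever meant for the training partition. The majority class is
    untouched; sequences and labels are never modified, only multiplicities.
    """
    counts = train.class_counts
    if min(counts.values()) == 0:
        raise ImbalanceError(f"cannot oversample with an empty class: {counts}")
    minority = min(counts, key=counts.get)
    majority = NON_CLASS if minority == DEG_CLASS else DEG_CLASS
    if counts[minority] == counts[majority]:
        return LabeledSet(list(train.records))
    rng = np.random.default_rng(seed)
    minority_records = [r for r in train.records if r.label == minority]
    extra = counts[majority] - counts[minority]
    picks = rng.integers(0, len(minority_records), size=extra)
    new_records = list(train.records) + [minority_records[i] for i in picks]
    return LabeledSet(new_records)


def inject_spike(
    labeled: LabeledSet, spike_seq: str = "AAGGG", target_class: int = DEG_CLASS
) -> tuple[LabeledSet, int]:
    """Overwrite the first ``len(spike_seq)`` bases of the upstream window of
    every record of ``target_class`` with ``spike_seq``.

    A deterministic positive control: after injection the target class is
    perfectly identified by a fixed-position motif. Idempotent. Returns the
    new set and the number of records modified.
    """
    if not spike_seq or set(spike_seq) - set("ACGT"):
        raise ValueError(f"spike sequence must be a nonempty ACGT string, got {spike_seq!r}")
    new_records: list[RegulatoryInput] = []
    n_modified = 0
    for r in labeled.records:
        if r.label == target_class:
            upstream = r.sequences[0]
            if len(spike_seq) > len(upstream):
                raise ValueError("spike longer than the upstream window")
            spiked = spike_seq + upstream[len(spike_seq):]
            new_records.append(r.with_sequences((spiked,) + r.sequences[1:]))
            n_modified += 1
        else:
            new_records.append(r)
    return LabeledSet(new_records), n_modified


def partition_manifest(
    train: LabeledSet, validation: LabeledSet, test: LabeledSet
) -> pd.DataFrame:
    """TSV-ready manifest: one row per record with its partition name."""
    rows = []
    for name, part in (("train", train), ("validation", validation), ("test", test)):
        for r in part.records:
            rows.append((f"{r.gene_id}|{r.accession_id}", name))
    return pd.DataFrame(rows, columns=["record_id", "partition"])
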