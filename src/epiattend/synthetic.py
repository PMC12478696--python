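"""Synthetic paired enhancer/promoter datasets with planted interacting motifs.

The generator emulates the shape of Hi-C-derived benchmark sets used for
sequence-only interaction prediction: fixed-length pairs (3000 bp enhancer,
2000 bp promoter), a strong 1:20 positive:negative imbalance, and — unlike
real data — a known ground truth.  Every positive pair carries exactly one
enhancer-motif plant and one promoter-motif plant at uniformly random
admissible positions; the manifest records where, so downstream recovery of
the motifs and of the enhancer-region x promoter-region attention pairing
can be scored exactly.

Negatives are pure i.i.d. background by default.  With
``negative_mode="single_motif"`` half of the negatives (chosen at random)
carry exactly one of the two motifs, so that presence of a single motif no
longer separates the classes and a model must learn the *pairing*.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .records import SequencePairRecord, validate_records

BASES = np.array(list("ACGT"))

DEFAULT_ENH_LEN = 3000
DEFAULT_PROM_LEN = 2000


@dataclass(frozen=True)
class PlantedMotif:
    """A consensus motif planted into background sequence.

    mutation_rate is the per-position probability that the planted base is
    replaced by a uniform draw from the three other bases.
    """

    name: str
    consensus: str
    mutation_rate: float = 0.0

    def __post_init__(self):
        if not self.consensus:
            raise ValueError("motif consensus must be non-empty")
        bad = set(self.consensus.upper()) - set("ACGT")
        if bad:
            raise ValueError(f"motif consensus restricted to ACGT, got {sorted(bad)}")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError(f"mutation_rate must be in [0,1], got {self.mutation_rate}")
        object.__setattr__(self, "consensus", self.consensus.upper())

    def __len__(self) -> int:
        return len(self.consensus)

    def expected_pwm(self) -> np.ndarray:
        """4 x len probability matrix implied by consensus + mutation_rate.

        The consensus base keeps probability 1 - mu; each other base gets mu/3.
        """
        mu = self.mutation_rate
        pwm = np.full((4, len(self.consensus)), mu / 3.0)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for j, base in enumerate(self.consensus):
            pwm[idx[base], j] = 1.0 - mu
        return pwm


@dataclass
class PlantRecord:
    """Where a motif went in one generated record (0-based offsets)."""

    record_id: str
    label: int
    enh_motif: str | None = None
    enh_position: int | None = None
    prom_motif: str | None = None
    prom_position: int | None = None


@dataclass
class GroundTruthManifest:
    """Everything needed to audit a generated dataset."""

    seed: int
    n_pos: int
    neg_per_pos: int
    enh_len: int
    prom_len: int
    enh_motif: PlantedMotif | None
    prom_motif: PlantedMotif | None
    negative_mode: str
    plants: list[PlantRecord] = field(default_factory=list)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=1, sort_keys=True)

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def read(cls, path: str | os.PathLike) -> "GroundTruthManifest":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        for key in ("enh_motif", "prom_motif"):
            if payload[key] is not None:
                payload[key] = PlantedMotif(**payload[key])
        payload["plants"] = [PlantRecord(**p) for p in payload["plants"]]
        return cls(**payload)

    def plant_for(self, record_id: str) -> PlantRecord:
        for p in self.plants:
            if p.record_id == record_id:
                return p
        raise KeyError(record_id)


def sample_background(length: int, seed: int | np.random.Generator) -> str:
    """Uniform i.i.d. background sequence of the given length over ACGT."""
    if length < 0:
        raise ValueError(f"length must be non-negative, got {length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if length == 0:
        return ""
    return "".join(BASES[rng.integers(0, 4, size=length)])


def plant_motif(
    seq: str,
    motif: PlantedMotif,
    position: int,
    seed: int | np.random.Generator,
) -> str:
    """Overwrite seq[position : position+len(motif)] with a (mutated) copy of
    the consensus.  The rest of the sequence is untouched."""
    m = len(motif)
    if position < 0 or position + m > len(seq):
        raise ValueError(
            f"plant position {position} with motif length {m} out of range for sequence length {len(seq)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    window = np.array(list(motif.consensus))
    if motif.mutation_rate > 0:
        hit = rng.random(m) < motif.mutation_rate
        for j in np.flatnonzero(hit):
            others = [b for b in "ACGT" if b != window[j]]
            window[j] = others[rng.integers(0, 3)]
    return seq[:position] + "".join(window) + seq[position + m:]


def generate_dataset(
    n_pos: int,
    neg_per_pos: int,
    enh_motif: PlantedMotif,
    prom_motif: PlantedMotif,
    seed: int,
    enh_len: int = DEFAULT_ENH_LEN,
    prom_len: int = DEFAULT_PROM_LEN,
    negative_mode: str = "background",
    cell_line: str = "synthetic",
) -> tuple[list[SequencePairRecord], GroundTruthManifest]:
    """Generate a labeled dataset of enhancer/promoter pairs.

    Parameters
    ----------
    n_pos, neg_per_pos
        Number of positive pairs and negatives per positive (default study
        design is 1:20).
    enh_motif, prom_motif
        Motifs planted into every positive pair (one plant each, at a
        uniformly random admissible position).
    negative_mode
        ``"background"`` (default): negatives are pure background.
        ``"single_motif"``: a random half of negatives carry exactly one of
        the two motifs (never both), so single-motif presence is uninformative.

    Returns the shuffled record list and a :class:`GroundTruthManifest`.
    """
    if n_pos < 1:
        raise ValueError("n_pos must be >= 1")
    if neg_per_pos < 0:
        raise ValueError("neg_per_pos must be >= 0")
    if len(enh_motif) > enh_len or len(prom_motif) > prom_len:
        raise ValueError("motif longer than its target sequence")
    if negative_mode not in ("background", "single_motif"):
        raise ValueError(f"unknown negative_mode {negative_mode!r}")

    rng = np.random.default_rng(seed)
    manifest = GroundTruthManifest(
        seed=seed, n_pos=n_pos, neg_per_pos=neg_per_pos,
        enh_len=enh_len, prom_len=prom_len,
        enh_motif=enh_motif, prom_motif=prom_motif,
        negative_mode=negative_mode,
    )

    records: list[SequencePairRecord] = []
    for i in range(n_pos):
        rid = f"pos{i:06d}"
        epos = int(rng.integers(0, enh_len - len(enh_motif) + 1))
        ppos = int(rng.integers(0, prom_len - len(prom_motif) + 1))
        enh = plant_motif(sample_background(enh_len, rng), enh_motif, epos, rng)
        prom = plant_motif(sample_background(prom_len, rng), prom_motif, ppos, rng)
        records.append(SequencePairRecord(rid, enh, prom, 1, cell_line))
        manifest.plants.append(PlantRecord(rid, 1, enh_motif.name, epos, prom_motif.name, ppos))

    n_neg = n_pos * neg_per_pos
    for i in range(n_neg):
        rid = f"neg{i:06d}"
        enh = sample_background(enh_len, rng)
        prom = sample_background(prom_len, rng)
        plant = PlantRecord(rid, 0)
        if negative_mode == "single_motif" and rng.random() < 0.5:
            if rng.random() < 0.5:
                epos = int(rng.integers(0, enh_len - len(enh_motif) + 1))
                enh = plant_motif(enh, enh_motif, epos, rng)
                plant.enh_motif, plant.enh_position = enh_motif.name, epos
            else:
                ppos = int(rng.integers(0, prom_len - len(prom_motif) + 1))
                prom = plant_motif(prom, prom_motif, ppos, rng)
                plant.prom_motif, plant.prom_position = prom_motif.name, ppos
        records.append(SequencePairRecord(rid, enh, prom, 0, cell_line))
        manifest.plants.append(plant)

    order = rng.permutation(len(records))
    records = [records[j] for j in order]
    validate_records(records, enh_len, prom_len)
    return records, manifest
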