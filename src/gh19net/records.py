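"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout the package, matching the
PDB-style convention used by standard numbering schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in input sequences: the 20 canonical letters plus X
ALLOWED_RESIDUES = frozenset(CANONICAL_AA + "X")

ACTIVITY_LABELS = ("chitinase", "endolysin", "other")


@dataclass
class SequenceRecord:
    """One protein sequence with its bookkeeping metadata.

    Seed records are biochemically characterized or structurally solved
    sequences; they anchor subfamily and group labels downstream, so a seed
    must carry an activity label.
    """

    id: str
    residues: str
    description: str = ""
    is_seed: bool = False
    activity_label: str | None = None
    taxonomy: str | None = None
    truth_group: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = sorted(set(self.residues) - ALLOWED_RESIDUES)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-amino-acid characters: "
                + ", ".join(bad)
            )
        if self.is_seed and self.activity_label is None:
            raise ValueError(f"seed sequence {self.id!r} lacks an activity label")
        if self.activity_label is not None and self.activity_label not in ACTIVITY_LABELS:
            raise ValueError(
                f"unknown activity label {self.activity_label!r} for {self.id!r}; "
                f"expected one of {ACTIVITY_LABELS}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class RawHitRecord:
    """One profile-vs-sequence domain hit as read from a hit table."""

    seq_id: str
    profile_id: str
    score: float
    bias: float
    evalue: float
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"hit on {self.seq_id!r}: invalid coordinates "
                f"start={self.start}, end={self.end} (1-based inclusive)"
            )
        if self.evalue < 0:
            raise ValueError(f"hit on {self.seq_id!r}: negative E-value {self.evalue}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RunConfig:
    """Thresholds and alignment parameters for one pipeline run."""

    cluster_centroid_pct: float = 90.0
    subfamily_pct: float = 40.0
    group_pct: float = 60.0
    protein_entry_pct: float = 99.0
    conservation_pct: float = 65.0
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    min_fragment_len: int = 120
    max_evalue: float = 1e-5
    min_hit_len: int = 120
    max_bias_ratio: float = 0.1
    seed: int = 0
    loop_definitions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("cluster_centroid_pct", "subfamily_pct", "group_pct",
                     "protein_entry_pct", "conservation_pct"):
            v = getattr(self, name)
            if not (0 < v <= 100):
                raise ValueError(f"{name}={v} outside (0, 100]")
        if not (self.gap_open > self.gap_extend > 0):
            raise ValueError(
                f"require gap_open > gap_extend > 0, got {self.gap_open}, {self.gap_extend}"
            )


def check_unique_ids(records: list[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id: {rec.id!r}")
        seen.add(rec.id)
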