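"""Core data model: copy-number segments, SSNV calls and tumor samples.

Coordinates are 0-based, half-open internally.  A mutation at position p
belongs to segment [start, end) iff start <= p < end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional


VALID_SAMPLE_TYPES = ("primary", "metastasis", "relapse")
VALID_TMM = ("MYCN", "TERT", "ALT", "none", "multiple", "unknown")


@dataclass
class SegmentProfile:
    """A genomic segment with total copy number and allelic composition.

    Attributes
    ----------
    chrom : chromosome label ("1".."22", "X", "Y")
    start, end : base-pair coordinates (0-based, half-open)
    cn : total copy number (integer >= 0), or None if unassigned
    b_allele : B-allele count b with 0 <= b <= cn, or None
    coverage_ratio : tumor/control coverage ratio CR (dimensionless), optional
    baf : B-allele frequency in [0, 1], optional
    """

    chrom: str
    start: int
    end: int
    cn: Optional[int] = None
    b_allele: Optional[int] = None
    coverage_ratio: Optional[float] = None
    baf: Optional[float] = None

    def __post_init__(self) -> None:
        self.chrom = str(self.chrom)
        if self.end <= self.start:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if self.cn is not None:
            self.cn = int(self.cn)
            if self.cn < 0:
                raise ValueError("copy number must be >= 0")
        if self.b_allele is not None:
            self.b_allele = int(self.b_allele)
            if self.cn is not None and not (0 <= self.b_allele <= self.cn):
                raise ValueError(
                    f"B-allele count {self.b_allele} outside [0, {self.cn}]"
                )
        if self.baf is not None and not (0.0 <= self.baf <= 1.0):
            raise ValueError("BAF must lie in [0, 1]")

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    @property
    def is_autosomal(self) -> bool:
        return self.chrom not in ("X", "Y", "chrX", "chrY")


@dataclass
class MutationCall:
    """One somatic SNV with raw read support.

    n_var / n_ref are variant / reference read counts; segment_id links the
    mutation to the index of its containing segment (None = unassigned).
    """

    chrom: str
    pos: int
    n_var: int
    n_ref: int
    ref: str = "N"
    alt: str = "N"
    segment_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.chrom = str(self.chrom)
        if self.n_var < 1:
            raise ValueError("variant read count must be >= 1")
        if self.n_ref < 0:
            raise ValueError("reference read count must be >= 0")

    @property
    def depth(self) -> int:
        return self.n_var + self.n_ref

    @property
    def vaf(self) -> float:
        return self.n_var / self.depth


@dataclass
class TumorSample:
    """A tumor sample: metadata plus its segments and mutation calls."""

    sample_id: str
    purity: float
    ploidy: float
    segments: list = field(default_factory=list)
    mutations: list = field(default_factory=list)
    age_days: Optional[float] = None
    sample_type: str = "primary"
    tmm: str = "unknown"

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must lie in (0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if self.sample_type not in VALID_SAMPLE_TYPES:
            raise ValueError(f"sample_type must be one of {VALID_SAMPLE_TYPES}")
        if self.tmm not in VALID_TMM:
            raise ValueError(f"tmm must be one of {VALID_TMM}")

    def mutations_in_segment(self, seg_id: int) -> list:
        return [m for m in self.mutations if m.segment_id == seg_id]

    # ---- lossless JSON round-trip ------------------------------------
    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "purity": self.purity,
            "ploidy": self.ploidy,
            "age_days": self.age_days,
            "sample_type": self.sample_type,
            "tmm": self.tmm,
            "segments": [asdict(s) for s in self.segments],
            "mutations": [asdict(m) for m in self.mutations],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "TumorSample":
        return cls(
            sample_id=d["sample_id"],
            purity=d["purity"],
            ploidy=d["ploidy"],
            age_days=d.get("age_days"),
            sample_type=d.get("sample_type", "primary"),
            tmm=d.get("tmm", "unknown"),
            segments=[SegmentProfile(**s) for s in d["segments"]],
            mutations=[MutationCall(**m) for m in d["mutations"]],
        )

    @classmethod
    def from_json(cls, path) -> "TumorSample":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CnaEventReport:
    """Per-tumor copy-number event annotation flags."""

    ploidy_class: int  # 2, 3 or 4
    focal_amplification: bool = False
    homozygous_deletion: bool = False
    loss_1p: bool = False
    loss_11q: bool = False
    whole_gain: dict = field(default_factory=dict)  # chrom -> bool, chroms 1,2,7,17
    partial_gain: dict = field(default_factory=dict)  # arm -> bool, 1q,2p,7q,17q

    def to_dict(self) -> dict:
        return asdict(self)
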