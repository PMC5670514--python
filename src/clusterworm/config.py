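"""Pipeline parameter bundle shared by the CLI and the library entry point."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .engine import DEFAULT_PAGESIZE
from .graph import FILTER_AND, FILTER_OR
from .kmers import DOUBLE_STRANDED, STRAND_SPECIFIC

__all__ = ["PipelineParams"]


@dataclass
class PipelineParams:
    """Validated knobs for the full pipeline.

    k and the strand mode shape the graph; ``min_kmer_cov`` floors node
    abundance (1 = keep everything); ``min_contig_length`` suppresses short
    contigs in the report; ``filter_rule`` picks how the two endpoint
    maximality tests combine in edge filtering; the engine knobs control
    logical parallelism and out-of-core paging.
    """

    k: int = 25
    mode: str = STRAND_SPECIFIC
    min_kmer_cov: int = 1
    min_contig_length: int = 48
    filter_rule: str = FILTER_AND
    n_workers: int = 1
    pagesize: int = DEFAULT_PAGESIZE
    spill_dir: str | Path | None = None
    seed: int = 0
    keep_temp: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.mode not in (STRAND_SPECIFIC, DOUBLE_STRANDED):
            raise ValueError(f"unknown strand mode: {self.mode!r}")
        if self.min_kmer_cov < 1:
            raise ValueError("min_kmer_cov must be >= 1")
        if self.min_contig_length < 1:
            raise ValueError("min_contig_length must be >= 1")
        if self.filter_rule not in (FILTER_AND, FILTER_OR):
            raise ValueError(f"unknown filter rule: {self.filter_rule!r}")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.pagesize <= 0:
            raise ValueError("pagesize must be > 0")
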