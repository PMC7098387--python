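"""Central pipeline configuration.

Every procedural constant of the workflow lives here: the read-cleaning
rules (5 nt 5' clip, Q<28 3' trim with a 1 nt window, <75 nt discard, 10%
subsample), the extension cap (100 iterations), the control-region boundary
window (250 bp), the edge-contig coverage filter (>=20x), the circularity
terminal-repeat minimum (strictly >50 bp) and the conserved-region homology
thresholds (>80% identity, e-value < 1e-20).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Constants steering every stage of the minicircle pipeline."""

    clip5_nt: int = 5                  # bases removed from each mate's 5' end
    qual_cutoff: int = 28              # phred threshold for 3' trimming
    qual_window_nt: int = 1            # trimming window (terminal base only)
    min_read_len: int = 75             # mates shorter than this discard the pair
    subsample_frac: float = 0.10       # fraction of pairs kept for assembly
    max_extend_iters: int = 100        # iterative-extension cap
    upstream_window_nt: int = 250      # CR window upstream of the coding boundary
    min_edge_contig_cov: float = 20.0  # mean-coverage filter for edge contigs
    min_terminal_repeat_nt: int = 51   # circularity calls need repeats >50 bp
    min_cr_identity: float = 0.80      # conserved-block identity threshold
    max_cr_evalue: float = 1e-20       # conserved-block significance threshold
    rng_seed: int = 0

    # mapper thresholds (exposed because cross-circle read stealing in the
    # conserved CR is sensitive to them; see docs/methods.md)
    map_min_identity: float = 0.90
    map_min_anchor_nt: int = 40
    insert_mean_nt: int = 400
    insert_sd_nt: int = 40
    read_len_nt: int = 150
    max_contig_nt: int = 10000  # runaway-extension guard

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = (
            self.clip5_nt, self.qual_cutoff, self.qual_window_nt,
            self.min_read_len, self.max_extend_iters, self.upstream_window_nt,
        )
        if any(c < 0 for c in counts):
            raise ConfigError("counts must be >= 0")
        if not 0.0 < self.subsample_frac <= 1.0:
            raise ConfigError("subsample_frac must be in (0, 1]")
        if self.min_terminal_repeat_nt <= 50:
            raise ConfigError("terminal repeats must be strictly >50 nt")
        if not 0.0 < self.min_cr_identity <= 1.0:
            raise ConfigError("min_cr_identity must be in (0, 1]")
        if self.min_edge_contig_cov < 0:
            raise ConfigError("min_edge_contig_cov must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)
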