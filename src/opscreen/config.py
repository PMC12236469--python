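"""Run configuration: every threshold the pipeline uses, with its default.

Defaults follow the published analysis conditions of each dialect:

* ``lmna_single`` (single 12-mer barcode): consensus edit distance cap 1,
  synonymous-referenced profile normalization, 70% PCA variance target,
  EMD-based landmark calls.
* ``pten_dual`` (ordered pair of 8-mers): edit distance cap 2, all-variant
  normalization, 60% variance target, median-z landmark calls.

Shared defaults: barcodes in <10 cells and variants with <5 barcodes are
dropped; landmark calls need z > 2.5 and Bonferroni-corrected KS p < 0.01;
hit features need corrected p < 0.001 in >= 25 variants; kNN k = 25;
per-variant classifiers need >= 150 cells and use a stratified 8:1:1 split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .genotype import FilterConfig
from .profiles import SelectionConfig
from .readcall import ReadCallConfig
from .embedding import EmbedConfig


DIALECTS = ("lmna_single", "pten_dual")


@dataclass
class RunConfig:
    dialect: str = "lmna_single"
    seed: int = 0
    min_overlap_px: int = 8
    expand_distance: float = 25.0
    readcall: ReadCallConfig = field(default_factory=ReadCallConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    embed: EmbedConfig = field(default_factory=EmbedConfig)
    landmark_z_thresh: float = 2.5
    landmark_p_thresh: float = 0.01
    hit_alpha: float = 0.001
    hit_min_variants: int = 25
    classifier_min_cells: int = 150

    def __post_init__(self):
        if self.dialect not in DIALECTS:
            raise ValueError(f"dialect must be one of {DIALECTS}")
        if isinstance(self.readcall, dict):
            self.readcall = ReadCallConfig(**self.readcall)
        if isinstance(self.filters, dict):
            self.filters = FilterConfig(**self.filters)
        if isinstance(self.selection, dict):
            sel = dict(self.selection)
            if "blocklist" in sel:
                sel["blocklist"] = tuple(sel["blocklist"])
            self.selection = SelectionConfig(**sel)
        if isinstance(self.embed, dict):
            self.embed = EmbedConfig(**self.embed)
        if self.dialect == "pten_dual" and self.filters.max_edit == 1:
            self.filters.max_edit = 2

    @property
    def normalize_mode(self) -> str:
        return "synonymous" if self.dialect == "lmna_single" else "all"

    @property
    def variance_target(self) -> float:
        return 0.7 if self.dialect == "lmna_single" else 0.6

    @property
    def landmark_mode(self) -> str:
        return "lmna_emd" if self.dialect == "lmna_single" else "pten_median"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selection"]["blocklist"] = list(d["selection"]["blocklist"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
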