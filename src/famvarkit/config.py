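"""Pipeline-wide thresholds and VCF annotation field mapping.

All cutoffs used by the filtering and classification stages live here so
that a single YAML file can reconfigure the whole pipeline.  Defaults are
the values used throughout the analysis: GQ >= 10, depth >= 20, allele
fraction in [0.2, 0.8] for heterozygotes, MAF < 1%, >= 5 of 9 damaging
predictor votes, kinship >= 0.044, inbreeding F > 0.1, 500 bp CNV merge
window, CNV allele-frequency cutoffs of 0.1% (de novo) and 1%
(homozygous), pRec > 0.9 for novel homozygous candidates, and a 2%
mitochondrial heteroplasmy floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

import yaml

# GRCh38 pseudo-autosomal regions on chrX (1-based inclusive).
DEFAULT_PAR: Tuple[Tuple[int, int], ...] = ((10_001, 2_781_479), (155_701_383, 156_030_895))


@dataclass
class Thresholds:
    """Numeric cutoffs for every pipeline stage."""

    gq_min: int = 10
    dp_min: int = 20
    ab_low: float = 0.2
    ab_high: float = 0.8
    maf_max: float = 0.01
    cadd_min: float = 10.0
    mpc_min: float = 1.0
    dmiss_votes_min: int = 5
    kinship_min: float = 0.044       # inclusive: phi >= kinship_min
    inbreeding_min: float = 0.1      # exclusive: F > inbreeding_min
    kinship_min_sites: int = 1000
    cnv_window: int = 500
    cnv_min_callers: int = 2
    cnv_denovo_af_max: float = 0.001
    cnv_hom_af_max: float = 0.01
    cnv_reciprocal_overlap: float = 0.5
    prec_min: float = 0.9
    heteroplasmy_min: float = 0.02   # exclusive: fraction > heteroplasmy_min
    par_intervals: Tuple[Tuple[int, int], ...] = DEFAULT_PAR


@dataclass
class FieldMap:
    """Names of the INFO keys carrying annotations in the input VCF."""

    gene: str = "GENE"
    consequence: str = "CSQ"
    acmg: str = "ACMG"
    # database name -> INFO key holding its allele frequency
    af_keys: Dict[str, str] = field(default_factory=lambda: {
        "1000g": "AF_1000G",
        "gnomad": "AF_GNOMAD",
        "exac": "AF_EXAC",
        "qgp": "AF_QGP",
        "internal": "AF_INTERNAL",
    })
    cadd: str = "CADD"
    sift: str = "SIFT"
    pph2_hdiv: str = "PPH2_HDIV"
    pph2_hvar: str = "PPH2_HVAR"
    lrt: str = "LRT"
    mutation_assessor: str = "MA"
    mutation_taster: str = "MT_PRED"
    mpc: str = "MPC"
    provean: str = "PROVEAN"


@dataclass
class PipelineConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    fields: FieldMap = field(default_factory=FieldMap)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in (raw.get("thresholds") or {}).items():
            if not hasattr(cfg.thresholds, key):
                raise KeyError(f"unknown threshold {key!r}")
            setattr(cfg.thresholds, key, value)
        fld = raw.get("fields") or {}
        for key, value in fld.items():
            if not hasattr(cfg.fields, key):
                raise KeyError(f"unknown field-map entry {key!r}")
            setattr(cfg.fields, key, value)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"thresholds": asdict(self.thresholds),
                            "fields": asdict(self.fields)}, fh)


DEFAULT_CONFIG = PipelineConfig()
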