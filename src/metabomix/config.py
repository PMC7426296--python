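"""Pipeline configuration: defaults, YAML loading, and run manifests.

Defaults reproduce the analysis conditions the pipeline is built around:
posterior threshold 0.8 for identification, q-value thresholds of 0.15
(kidney) and 0.05 (plasma), a minimal 20% fold change (Fc >= 1.2), retention
time window 2-13 min with height > 1000 counts, a 50 ppm candidate capture
window, and p < 0.1 for the one-sided taxon comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import yaml

__all__ = ["PipelineConfig", "load_config", "write_manifest"]


@dataclass
class PipelineConfig:
    # paths
    database: Optional[str] = None
    peaks: Optional[str] = None
    design: Optional[str] = None
    taxa: Optional[str] = None
    taxa_design: Optional[str] = None
    outdir: str = "metabomix_out"
    # thresholds
    posterior_threshold: float = 0.8
    q_thresholds: Dict[str, float] = field(
        default_factory=lambda: {"kidney": 0.15, "plasma": 0.05}
    )
    fc_threshold: float = 1.2
    taxa_p_threshold: float = 0.1
    # filters
    rt_min: float = 2.0
    rt_max: float = 13.0
    min_height: float = 1000.0
    # matching
    adducts: Optional[List[str]] = None  # None -> polarity defaults
    capture_window_ppm: float = 50.0
    min_matches: int = 50
    #: set when the peak table already carries neutralized masses (no adduct
    #: enumeration; the mz column is matched as-is)
    masses_are_neutral: bool = False
    #: fit the mixture on signed errors (default) or folded absolute errors
    error_mode: str = "signed"
    # statistics
    t_variant: str = "student"
    qvalue_lambda: float = 0.5
    fc_means: str = "arithmetic"  # or "geometric"
    # taxa
    taxa_rank: str = "genus"
    taxa_factor: str = "genotype"
    taxa_group_a: str = "WT"
    taxa_group_b: str = "KO"
    # contrasts: list of {factor, numerator, denominator, within?}
    contrasts: List[Dict] = field(
        default_factory=lambda: [
            {"factor": "genotype", "numerator": "KO", "denominator": "WT"}
        ]
    )
    organ: str = "kidney"
    seed: int = 1
    # synthetic-data overrides passed through to SimConfig
    simulate: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.posterior_threshold <= 1.0:
            raise ValueError(
                f"posterior_threshold must lie in (0, 1], got {self.posterior_threshold}"
            )
        if not 0.0 < self.qvalue_lambda < 1.0:
            raise ValueError("qvalue_lambda must lie in (0, 1)")

    @property
    def q_threshold(self) -> float:
        return self.q_thresholds.get(self.organ, 0.15)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


def load_config(path: Optional[Union[str, Path]] = None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    An unknown key in the file or the overrides is an error naming the key.
    """
    data: Dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    return PipelineConfig(**data)


def write_manifest(config: PipelineConfig, outdir: Union[str, Path]) -> Path:
    """Echo the config into the output directory with a content hash.

    The hash covers the canonical JSON of the config (seed included), so two
    runs with identical manifests are bit-exact reruns of the deterministic
    stages.
    """
    import numpy
    import pandas
    import scipy

    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "metabomix": __version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
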