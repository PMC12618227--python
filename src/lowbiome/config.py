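"""Single-file YAML pipeline configuration.

One config block per stage; unknown keys are rejected on load so typos fail
loudly. All defaults are the pipeline's shipped operating values: 0.045% and
8.3% filtration fallbacks, the >20 pseudo-positive cutoff, 30 µm and 100 µm
neighborhood radii, 2 geometric SDs for the LOQ, 10% detection rates and the
SNR > 2 protein gate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    amplicon: dict = field(
        default_factory=lambda: {
            "proportion_cutoff": 0.00045,
            "prevalence_cutoff": 0.083,
            "derive_thresholds": True,
            "detection_min": 1,
        }
    )
    spatial: dict = field(
        default_factory=lambda: {
            "pseudo_positive_cutoff": 20.0,
            "nh_radius_um": 30.0,
            "excl_radius_um": 100.0,
            "min_total_transcripts": 20,
        }
    )
    dsp: dict = field(
        default_factory=lambda: {
            "n_sd": 2,
            "min_roi_detection_rate": 0.10,
            "min_target_detection_rate": 0.10,
            "protein_min_snr": 2.0,
            "protein_min_roi_fraction": 0.10,
        }
    )
    shotgun: dict = field(default_factory=lambda: {"max_depth": 2.0, "median_override": None})
    overlap: dict = field(
        default_factory=lambda: {"species_identity": 95.0, "genome_identity": 98.0}
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for section, values in data.items():
            if section == "seed":
                cfg.seed = int(values)
                continue
            if not hasattr(cfg, section):
                raise ConfigError(f"unknown config section {section!r}")
            block = getattr(cfg, section)
            if not isinstance(values, dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            for key, v in values.items():
                if key not in block:
                    raise ConfigError(f"unknown key {section}.{key}")
                block[key] = v
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
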