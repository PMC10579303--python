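"""Run configuration: thresholds, copy model, seeds, and IO paths.

Defaults reproduce the pipeline's canonical parameters: dereplication at
100% identity (80% for the hypervariable NirK), read mapping at 90%
identity / 60% coverage, family assignment at 85% identity, a strict 1:1
activity threshold, a 10-fold divergence cutoff, and a [0.5, 2] consistency
band for single-copy gene:rpoB ratios.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from ._exceptions import ConfigurationError
from .abundance import CopyModel


@dataclass(frozen=True)
class Thresholds:
    derep_identity: float = 1.0
    derep_identity_by_marker: Mapping[str, float] = field(
        default_factory=lambda: {"nirK": 0.8})
    map_identity: float = 0.90
    map_coverage: float = 0.60
    assign_min_identity: float = 0.85
    activity_threshold: float = 1.0
    fold_cutoff: float = 10.0
    single_copy_band: tuple[float, float] = (0.5, 2.0)

    def validate(self) -> None:
        for name in ("derep_identity", "map_identity", "map_coverage",
                     "assign_min_identity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name}={v} outside (0, 1]")
        for m, v in self.derep_identity_by_marker.items():
            if not 0 < v <= 1:
                raise ConfigurationError(
                    f"derep identity for {m}={v} outside (0, 1]")
        if self.activity_threshold < 0:
            raise ConfigurationError("activity_threshold must be >= 0")
        if self.fold_cutoff <= 1:
            raise ConfigurationError("fold_cutoff must exceed 1")
        lo, hi = self.single_copy_band
        if not 0 < lo <= 1 <= hi:
            raise ConfigurationError(
                "single_copy_band must bracket 1 with a positive lower edge")

    def derep_threshold(self, marker: str) -> float:
        return self.derep_identity_by_marker.get(marker,
                                                 self.derep_identity)


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a synthetic end-to-end quantification run."""

    seed: int = 0
    profile: str = "soil-like"
    n_lineages: int = 6
    depth_dna: int = 1_000_000
    depth_rna: int = 1_000_000
    mode: str = "sampled"
    phylotypes_per_lineage: int = 2
    divergence: float = 0.05
    thresholds: Thresholds = field(default_factory=Thresholds)
    copy_model_overrides: Mapping[str, float] = field(default_factory=dict)
    outdir: str = "nitriquant_run"

    def validate(self) -> None:
        self.thresholds.validate()
        if self.n_lineages < 1:
            raise ConfigurationError("n_lineages must be >= 1")
        if self.depth_dna <= 0 or self.depth_rna <= 0:
            raise ConfigurationError("depths must be positive")
        if self.mode not in ("sampled", "expected"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not 0 <= self.divergence < 1:
            raise ConfigurationError("divergence must be in [0, 1)")
        if self.phylotypes_per_lineage < 1:
            raise ConfigurationError("phylotypes_per_lineage must be >= 1")
        self.copy_model()  # validates overrides

    def copy_model(self) -> CopyModel:
        return CopyModel.from_mapping(self.copy_model_overrides)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["thresholds"]["derep_identity_by_marker"] = dict(
            self.thresholds.derep_identity_by_marker)
        d["thresholds"]["single_copy_band"] = list(
            self.thresholds.single_copy_band)
        d["copy_model_overrides"] = dict(self.copy_model_overrides)
        return d

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON form; stamped into every output.

        IO paths are excluded: the hash identifies the scientific
        configuration, so identical runs in different directories produce
        byte-identical tables.
        """
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        thr = d.pop("thresholds", {})
        if isinstance(thr, Mapping):
            thr = dict(thr)
            if "single_copy_band" in thr:
                thr["single_copy_band"] = tuple(thr["single_copy_band"])
            thresholds = Thresholds(**thr)
        else:
            thresholds = thr
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(thresholds=thresholds, **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)
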