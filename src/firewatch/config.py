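"""Flat key-value pipeline configuration with YAML round-trip."""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .co_monitor import CoConfig
from .fall_detector import FallConfig
from .lopp_detector import LoppConfig


@dataclass
class PipelineConfig:
    """Every tunable of the detection stack, in the units of the field.

    Thresholds are expressed in seconds/g/meters/ppm so the same file works
    at 100 Hz and 25 Hz; conversion to samples happens inside the detectors.
    Unknown keys in a config file are rejected.
    """

    # ingest
    acc_units: str = "ms2"          # "ms2" or "g"
    axis_map: str = "+x,+y,+z"      # device-mount remap applied at ingest

    # barometric altimetry
    p0_hpa: float = 1013.25
    baro_exponent_denominator: float = 5.225
    kalman_r: float = 1.0
    kalman_q: float = 0.01
    kalman_p_init: float = 1.0

    # fall cascade
    uth_g: float = 1.8
    upt_g: float = 1.25
    lpt_g: float = 0.75
    postfall_delay_s: float = 3.0
    postfall_window_s: float = 2.0
    posture_recheck_s: float = 0.5
    refractory_s: float = 6.0
    theta_th_deg: float = 25.0
    pitch_th_deg: float = 30.0
    roll_th_deg: float = 30.0
    madgwick_beta: float = 0.1
    theta_source: str = "raw"       # "raw" or "filtered"
    algorithm: str = "algorithm1"

    # LOPP
    lu_mov_g: float = 1.2
    ll_mov_g: float = 0.8
    lopp_window_s: float = 4.0
    alt_band_m: float = 0.5

    # CO
    co_alert_ppm: float = 33.0
    co_reference_ppm: float = 35.0
    co_hold_s: float = 2.0

    # detector toggles
    detect_fall: bool = True
    detect_lopp: bool = True
    detect_co: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def load_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a flat mapping")
        return cls.from_dict(data)

    def save_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # detector-config views ------------------------------------------------

    def fall_config(self) -> FallConfig:
        return FallConfig(
            uth=self.uth_g,
            upt=self.upt_g,
            lpt=self.lpt_g,
            postfall_delay=self.postfall_delay_s,
            postfall_window=self.postfall_window_s,
            posture_recheck=self.posture_recheck_s,
            refractory=self.refractory_s,
            theta_th_deg=self.theta_th_deg,
            pitch_th_deg=self.pitch_th_deg,
            roll_th_deg=self.roll_th_deg,
        )

    def lopp_config(self) -> LoppConfig:
        return LoppConfig(
            lu_mov=self.lu_mov_g,
            ll_mov=self.ll_mov_g,
            window=self.lopp_window_s,
            alt_band=self.alt_band_m,
        )

    def co_config(self) -> CoConfig:
        return CoConfig(
            alert_ppm=self.co_alert_ppm,
            reference_hazard_ppm=self.co_reference_ppm,
            hold_s=self.co_hold_s,
            kalman_r=self.kalman_r,
            kalman_q=self.kalman_q,
            kalman_p_init=self.kalman_p_init,
        )
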