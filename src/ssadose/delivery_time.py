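"""Additional treatment-delivery-time model for the moving aperture.

The aperture must reposition between consecutive spots, so the delivery
overhead grows with the spot count: t_add = N * x / v with N spots, spot
spacing x, and constant motor speed v.  Acceleration and deceleration are
deliberately ignored (they require hardware characterization).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TimingParams", "additional_time"]


@dataclass(frozen=True)
class TimingParams:
    n_spots: int
    spot_spacing_mm: float
    motor_speed_mm_s: float

    def __post_init__(self) -> None:
        if self.n_spots < 0:
            raise ValueError("n_spots must be non-negative")
        if self.spot_spacing_mm <= 0:
            raise ValueError("spot_spacing_mm must be positive")
        if self.motor_speed_mm_s <= 0:
            raise ValueError("motor_speed_mm_s must be positive")


def additional_time(params: TimingParams) -> float:
    """Added delivery time in seconds: N * x / v."""
    return params.n_spots * params.spot_spacing_mm / params.motor_speed_mm_s
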