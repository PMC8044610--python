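"""Idealized echo-delay geometry of the click-and-reflector setup.

A loudspeaker between the listener's ears and the reflecting disk emits a
click; the listener hears the direct click and, later, its reflection off
the disk. In the collinear idealization (source, ears and disk on one
line) the interclick interval (ICI, also called echo delay) is the
reflected-path excess over the direct path divided by the speed of sound:

    ICI = 2 * (ear_to_disk - ear_to_speaker) / speed_of_sound

so the delay grows by 2/speed seconds — about 5.8 ms, or roughly 6 ms,
per meter of reflector distance at 343 m/s. The small lateral offset of
the real disks (18 degrees) is ignored; its path-length effect is under 5%.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GeometryConfig", "predicted_ici", "ici_slope"]

#: Speed of sound in dry air at 20 degrees C, m/s.
DEFAULT_SPEED_OF_SOUND = 343.0


@dataclass(frozen=True)
class GeometryConfig:
    """Collinear ear-speaker-disk arrangement (distances in meters)."""

    ear_to_disk_m: float
    ear_to_speaker_m: float = 0.0
    speed_of_sound_m_s: float = DEFAULT_SPEED_OF_SOUND

    def __post_init__(self) -> None:
        if not 0.0 <= self.ear_to_speaker_m <= self.ear_to_disk_m:
            raise ValueError(
                "require 0 <= ear_to_speaker_m <= ear_to_disk_m "
                f"(got {self.ear_to_speaker_m} vs {self.ear_to_disk_m})"
            )
        if self.speed_of_sound_m_s <= 0:
            raise ValueError("speed_of_sound_m_s must be positive")


def predicted_ici(config: GeometryConfig) -> float:
    """Interclick interval in milliseconds for a collinear geometry.

    Reflected path (speaker -> disk -> ear) minus direct path (speaker ->
    ear), over the speed of sound: 2 * (ear_to_disk - ear_to_speaker) / v.
    """
    return (
        1000.0
        * 2.0
        * (config.ear_to_disk_m - config.ear_to_speaker_m)
        / config.speed_of_sound_m_s
    )


def ici_slope(speed_of_sound_m_s: float = DEFAULT_SPEED_OF_SOUND) -> float:
    """Echo-delay growth per meter of reflector distance, ms/m (= 2000/v)."""
    if speed_of_sound_m_s <= 0:
        raise ValueError("speed_of_sound_m_s must be positive")
    return 1000.0 * 2.0 / speed_of_sound_m_s
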