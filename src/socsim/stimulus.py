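"""Binaural sound-stimulus descriptor and interaural timing geometry.

The simulator drives every fiber with a single pure tone characterized by
frequency, sound pressure level, duration, and interaural time difference
(ITD).  The sign convention, fixed once and used everywhere, is

    itd = (right-ear arrival) - (left-ear arrival)

so a positive ITD means the sound source is on the left and the left ear
leads.
"""

from __future__ import annotations

from dataclasses import dataclass

ITD_MAX_MS = 2.0


@dataclass(frozen=True)
class SoundStimulus:
    """A pure-tone binaural stimulus.

    Parameters
    ----------
    frequency_hz : float
        Tone frequency in Hz (physiological ITD coding range, 20-1500 Hz).
    level_db : float
        Sound pressure level in dB SPL.
    duration_ms : float
        Stimulus duration in ms.
    itd_ms : float
        Interaural time difference in ms; positive when the sound comes
        from the left (left ear leads).
    """

    frequency_hz: float
    level_db: float
    duration_ms: float
    itd_ms: float = 0.0

    def __post_init__(self) -> None:
        if not self.frequency_hz > 0:
            raise ValueError(f"frequency must be positive, got {self.frequency_hz}")
        if not self.duration_ms > 0:
            raise ValueError(f"duration must be positive, got {self.duration_ms}")
        if abs(self.itd_ms) > ITD_MAX_MS:
            raise ValueError(
                f"|itd| must be <= {ITD_MAX_MS} ms, got {self.itd_ms}"
            )

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.frequency_hz

    def with_itd(self, itd_ms: float) -> "SoundStimulus":
        return SoundStimulus(self.frequency_hz, self.level_db, self.duration_ms, itd_ms)


def ear_arrival_offsets(itd_ms: float) -> tuple[float, float]:
    """Arrival-time offsets (left, right) in ms for a given ITD.

    The leading ear has offset 0 and the lagging ear |itd|; for itd > 0 the
    left ear leads.
    """
    if abs(itd_ms) > ITD_MAX_MS:
        raise ValueError(f"|itd| must be <= {ITD_MAX_MS} ms, got {itd_ms}")
    if itd_ms >= 0:
        return 0.0, float(itd_ms)
    return float(-itd_ms), 0.0
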