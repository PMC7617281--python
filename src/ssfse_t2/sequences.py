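"""Acquisition parameter descriptions for SS-FSE and MESE echo trains.

A single-shot fast spin echo (SS-FSE) acquisition collects every
phase-encode line of a 2D slice from one excitation followed by a long
refocusing train.  With linear phase-encode ordering the train starts at
the truncated edge of k-space and passes through the k-space centre, so
the partial-Fourier ("halfscan") factor controls the echo at which the
centre line — and therefore the effective echo time — is acquired.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = ["SequenceParams", "echo_index_for_te", "TABLE_PRESETS"]


@dataclass(frozen=True)
class SequenceParams:
    """Parameters of one SS-FSE contrast (one effective TE).

    Parameters
    ----------
    te : float
        Nominal echo time in ms (the label of the contrast).  The echo
        actually encoding the k-space centre is derived from ``halfscan``
        via :func:`echo_index_for_te` and may differ from the nominal
        label by up to one echo spacing; ``te_actual`` reports it.
    tr : float
        Repetition time in ms.  Shot TRs here are tens of seconds, so
        echo trains are simulated from thermal equilibrium.
    esp : float
        Echo spacing in ms.
    tse_factor : int
        Echo train length (number of acquired phase-encode lines).
    halfscan : float
        Partial-Fourier fraction of the fully sampled k-space, in
        (0.5, 1].
    matrix : int
        Reconstruction matrix size along phase encode.
    sense : float
        Parallel-imaging acceleration factor; the fully sampled line
        count is ``matrix / sense``.
    slice_thickness : float
        Excited slice thickness in mm.
    excitation_flip, first_refocus_flip, steady_refocus_flip : float
        Nominal flip angles in degrees.  The scanner's proprietary
        refocusing schedule is not public; the train is modelled with
        one excitation profile, one first-refocusing profile and one
        steady profile reused for the rest of the train, each obtained
        by Bloch simulation of the slice-selective pulse.
    pulse_duration : float
        RF pulse duration in ms used for the slice-profile simulation.
    time_bandwidth : float
        Time-bandwidth product of the RF pulses.
    """

    te: float
    tr: float = 20000.0
    esp: float = 6.1
    tse_factor: int = 99
    halfscan: float = 0.709
    matrix: int = 288
    sense: float = 2.0
    slice_thickness: float = 2.5
    excitation_flip: float = 90.0
    first_refocus_flip: float = 180.0
    steady_refocus_flip: float = 180.0
    pulse_duration: float = 3.0
    time_bandwidth: float = 4.0

    def __post_init__(self) -> None:
        if not (0.5 < self.halfscan <= 1.0):
            raise ValueError(f"halfscan must lie in (0.5, 1], got {self.halfscan}")
        if self.esp <= 0 or self.te <= 0 or self.slice_thickness <= 0:
            raise ValueError("te, esp and slice_thickness must be positive")
        if self.tse_factor < 1:
            raise ValueError("tse_factor must be >= 1")

    @property
    def n_full_lines(self) -> int:
        """Fully sampled phase-encode line count, matrix / SENSE."""
        return int(round(self.matrix / self.sense))

    @property
    def te_actual(self) -> float:
        """Echo time actually realised by the centre-line echo (ms)."""
        return echo_index_for_te(self) * self.esp

    @classmethod
    def from_te_preset(cls, te: float, **overrides) -> "SequenceParams":
        """Return the scanner preset for a nominal TE of 80, 180 or 400 ms."""
        try:
            preset = TABLE_PRESETS[int(te)]
        except KeyError:
            raise KeyError(
                f"no preset for TE={te}; available: {sorted(TABLE_PRESETS)}"
            ) from None
        preset = dict(preset)
        preset.update(overrides)
        return cls(**preset)

    @classmethod
    def derive_for_te(cls, te: float, base_te: float = 180.0, **overrides) -> "SequenceParams":
        """Construct parameters realising an arbitrary TE.

        Keeps echo spacing and geometry of the ``base_te`` preset and
        chooses the halfscan factor so the centre-line echo lands within
        one echo spacing of the requested TE; the train then runs to the
        far edge of k-space.
        """
        base = cls.from_te_preset(base_te)
        n_full = base.n_full_lines
        index = int(round(te / base.esp))
        if index < 1:
            raise ValueError(f"TE={te} shorter than one echo spacing")
        halfscan = 0.5 + index / n_full
        if halfscan > 1.0:
            raise ValueError(f"TE={te} not achievable within the echo train")
        tse_factor = n_full // 2 + index
        params = dataclasses.asdict(base)
        params.update(te=te, halfscan=halfscan, tse_factor=tse_factor)
        params.update(overrides)
        return cls(**params)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceParams":
        return cls(**d)


#: Scanner presets for the three clinical contrasts (1.5 T SS-FSE).
TABLE_PRESETS: dict[int, dict] = {
    80: dict(te=80.0, tr=17800.0, esp=6.2, halfscan=0.587, tse_factor=82),
    180: dict(te=180.0, tr=21400.0, esp=6.1, halfscan=0.709, tse_factor=99),
    400: dict(te=400.0, tr=29100.0, esp=6.1, halfscan=0.966, tse_factor=135),
}


def echo_index_for_te(seq: SequenceParams) -> int:
    """Echo (1-based) at which the centre of k-space is encoded.

    With linear ordering over ``n_full = matrix / sense`` line positions,
    partial Fourier truncates the first ``(1 - halfscan) * n_full`` lines,
    so the centre line is reached after ``(halfscan - 0.5) * n_full``
    echoes.  The result is clipped into the acquired train.
    """
    n_full = seq.n_full_lines
    index = int(round((seq.halfscan - 0.5) * n_full))
    index = max(index, 1)
    if index > seq.tse_factor:
        raise ValueError(
            f"centre-line echo {index} exceeds echo train length {seq.tse_factor}"
        )
    te_actual = index * seq.esp
    if abs(te_actual - seq.te) > seq.esp:
        logger.info(
            "nominal TE %.0f ms realised at echo %d (TE %.1f ms)",
            seq.te, index, te_actual,
        )
    return index
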