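"""Acquisition protocol descriptions for the five simulated sequences.

A protocol is a frozen record of the timing constants and sampling scheme of
one acquisition.  The constants default to the preclinical 7 T protocol this
package emulates: IR-TrueFISP (TE 1.7 / TR 3.4 ms) for joint T1/T2, MT-RARE
(TE 19.22 / TR 1500 ms, 25 ppm on / 100 ppm off) for MTR, respiratory-style
DWI with five b-values between 200 and 1000 s/mm^2, an 8-echo MGE train with
3 ms spacing for R2*, and a 1 kHz MRE acquisition with 4 wave phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODALITIES = ("IR_TRUEFISP", "MT_RARE", "DWI", "MGE", "MRE")

#: default inversion-time sampling for IR-TrueFISP (ms), log-spaced 30-5000 ms.
#: The source protocol does not state its inversion-time scheme; the choice is
#: recorded here, on the protocol object, and shared by simulator and fitter.
DEFAULT_INVERSION_TIMES_MS = (
    30.0, 47.8, 76.1, 121.1, 192.9, 307.1, 489.0, 778.7, 1239.9, 1974.2, 3143.5, 5005.5,
)

#: default TrueFISP excitation flip angle (degrees); recorded, not inferred.
DEFAULT_FLIP_DEG = 70.0


@dataclass(frozen=True)
class AcquisitionProtocol:
    """One acquisition's timing, sampling and noise description.

    ``noise_sigma`` is the Rician noise scale expressed relative to the mean
    viable-tissue signal (Gaussian on real/imaginary displacement parts for
    MRE); ``seed`` drives that noise.
    """

    modality: str
    te_ms: float
    tr_ms: float
    inversion_times_ms: tuple[float, ...] = ()
    flip_deg: float = DEFAULT_FLIP_DEG
    b_values: tuple[float, ...] = ()
    echo_times_ms: tuple[float, ...] = ()
    mt_offsets_ppm: tuple[float, float] = ()
    mre_frequency_hz: float = 0.0
    n_wave_phases: int = 0
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.modality == "IR_TRUEFISP":
            if len(self.inversion_times_ms) < 4:
                raise ValueError("IR-TrueFISP needs >= 4 inversion times")
            if any(np.diff(self.inversion_times_ms) <= 0):
                raise ValueError("inversion times must be strictly increasing")
            if not 0 < self.flip_deg < 180:
                raise ValueError("flip angle must lie in (0, 180) degrees")
        elif self.modality == "DWI":
            b = np.asarray(self.b_values, dtype=float)
            if b.size < 2:
                raise ValueError("DWI needs >= 2 b-values")
            if np.any(np.diff(b) <= 0):
                raise ValueError("b-values must be strictly increasing")
            if b.min() < 200 or b.max() > 1000:
                raise ValueError("b-values must lie within [200, 1000] s/mm^2")
        elif self.modality == "MGE":
            te = np.asarray(self.echo_times_ms, dtype=float)
            if te.size < 3:
                raise ValueError("MGE needs >= 3 echoes")
            d = np.diff(te)
            if not np.allclose(d, d[0]) or not np.isclose(te[0], d[0]):
                raise ValueError(
                    "echo times must be arithmetic with first echo equal to the spacing"
                )
        elif self.modality == "MT_RARE":
            if len(self.mt_offsets_ppm) != 2:
                raise ValueError("MT-RARE needs (on, off) offset frequencies")
        elif self.modality == "MRE":
            if self.mre_frequency_hz <= 0:
                raise ValueError("mre_frequency_hz must be positive")
            if self.n_wave_phases < 3:
                raise ValueError("n_wave_phases must be >= 3")

    @property
    def n_frames(self) -> int:
        return {
            "IR_TRUEFISP": len(self.inversion_times_ms),
            "MT_RARE": 2,
            "DWI": len(self.b_values),
            "MGE": len(self.echo_times_ms),
            "MRE": self.n_wave_phases,
        }[self.modality]


def ir_truefisp_protocol(
    inversion_times_ms: tuple[float, ...] = DEFAULT_INVERSION_TIMES_MS,
    flip_deg: float = DEFAULT_FLIP_DEG,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> AcquisitionProtocol:
    return AcquisitionProtocol(
        modality="IR_TRUEFISP",
        te_ms=1.7,
        tr_ms=3.4,
        inversion_times_ms=tuple(inversion_times_ms),
        flip_deg=flip_deg,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def mt_rare_protocol(noise_sigma: float = 0.0, seed: int | None = None) -> AcquisitionProtocol:
    return AcquisitionProtocol(
        modality="MT_RARE",
        te_ms=19.22,
        tr_ms=1500.0,
        mt_offsets_ppm=(25.0, 100.0),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def dwi_protocol(
    b_values: tuple[float, ...] = (200.0, 400.0, 600.0, 800.0, 1000.0),
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> AcquisitionProtocol:
    return AcquisitionProtocol(
        modality="DWI",
        te_ms=37.88,
        tr_ms=1500.0,
        b_values=tuple(b_values),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def mge_protocol(
    echo_times_ms: tuple[float, ...] = (3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0, 24.0),
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> AcquisitionProtocol:
    return AcquisitionProtocol(
        modality="MGE",
        te_ms=3.0,
        tr_ms=200.0,
        echo_times_ms=tuple(echo_times_ms),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def mre_protocol(
    mre_frequency_hz: float = 1000.0,
    n_wave_phases: int = 4,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> AcquisitionProtocol:
    return AcquisitionProtocol(
        modality="MRE",
        te_ms=30.0,
        tr_ms=504.0,
        mre_frequency_hz=mre_frequency_hz,
        n_wave_phases=n_wave_phases,
        noise_sigma=noise_sigma,
        seed=seed,
    )
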