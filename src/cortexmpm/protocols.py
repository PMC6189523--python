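"""FLASH acquisition protocol descriptions and the two scanner presets.

Angles are stored in degrees in configuration and converted to radians at
the point of use.  Repetition and echo times are stored in milliseconds;
relaxation rates everywhere in the package are in s^-1, so every formula
converts TR/TE to seconds explicitly (see :func:`tr_seconds`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "WeightingProtocol",
    "AcquisitionProtocol",
    "cohort1_protocol",
    "cohort2_protocol",
    "get_protocol",
    "WEIGHTINGS",
]

#: canonical weighting order used throughout the package
WEIGHTINGS = ("PDw", "T1w", "MTw")


def _echo_train(te1_ms: float, dte_ms: float, n: int) -> tuple[float, ...]:
    return tuple(round(te1_ms + i * dte_ms, 6) for i in range(n))


@dataclass(frozen=True)
class WeightingProtocol:
    """Sequence settings of one weighted multi-echo FLASH acquisition."""

    flip_angle_deg: float
    tr_ms: float
    te_ms: tuple[float, ...]
    mt_pulse: bool = False

    @property
    def flip_angle_rad(self) -> float:
        return math.radians(self.flip_angle_deg)

    @property
    def tr_s(self) -> float:
        return self.tr_ms / 1000.0

    @property
    def te_s(self) -> tuple[float, ...]:
        return tuple(t / 1000.0 for t in self.te_ms)

    @property
    def n_echoes(self) -> int:
        return len(self.te_ms)

    def validate(self) -> None:
        if not 0.0 < self.flip_angle_rad < math.pi / 2:
            raise ValueError(
                f"flip angle must lie in (0, 90) degrees, got {self.flip_angle_deg}"
            )
        if len(self.te_ms) < 1:
            raise ValueError("at least one echo time is required")
        if any(b <= a for a, b in zip(self.te_ms, self.te_ms[1:])):
            raise ValueError(f"echo times must be strictly increasing: {self.te_ms}")
        if self.tr_ms <= max(self.te_ms):
            raise ValueError(
                f"TR ({self.tr_ms} ms) must exceed the longest TE ({max(self.te_ms)} ms)"
            )


@dataclass(frozen=True)
class AcquisitionProtocol:
    """The three-weighting FLASH protocol (PDw / T1w / MTw)."""

    weightings: dict[str, WeightingProtocol]
    cohort_id: int = 1
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = [w for w in WEIGHTINGS if w not in self.weightings]
        if missing:
            raise ValueError(f"protocol missing weightings: {missing}")
        for w, wp in self.weightings.items():
            wp.validate()
            if wp.mt_pulse and w != "MTw":
                raise ValueError(f"mt_pulse set on non-MT weighting {w!r}")
        if not self.weightings["MTw"].mt_pulse:
            raise ValueError("MTw weighting must carry the MT pre-pulse flag")
        n_pd = self.weightings["PDw"].n_echoes
        n_t1 = self.weightings["T1w"].n_echoes
        n_mt = self.weightings["MTw"].n_echoes
        if n_pd != n_t1:
            raise ValueError("PDw and T1w must have the same number of echoes")
        if n_mt > n_pd:
            raise ValueError("MTw may not have more echoes than PDw")
        if self.cohort_id not in (1, 2):
            raise ValueError("cohort_id must be 1 or 2")

    def __getitem__(self, w: str) -> WeightingProtocol:
        return self.weightings[w]

    @property
    def n_echoes_for_averaging(self) -> int:
        """Echoes entering the SNR-boosting average (6 for cohort 2, else all)."""
        return 6 if self.cohort_id == 2 else self.weightings["PDw"].n_echoes

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cohort_id": self.cohort_id,
            "weightings": {
                w: {
                    "flip_angle_deg": wp.flip_angle_deg,
                    "tr_ms": wp.tr_ms,
                    "te_ms": list(wp.te_ms),
                    "mt_pulse": wp.mt_pulse,
                }
                for w, wp in self.weightings.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(
            weightings={
                w: WeightingProtocol(
                    flip_angle_deg=s["flip_angle_deg"],
                    tr_ms=s["tr_ms"],
                    te_ms=tuple(s["te_ms"]),
                    mt_pulse=bool(s.get("mt_pulse", False)),
                )
                for w, s in d["weightings"].items()
            },
            cohort_id=int(d.get("cohort_id", 1)),
            name=d.get("name", "custom"),
        )


def cohort1_protocol() -> AcquisitionProtocol:
    """First scanner preset: 5/29 deg PDw/T1w at TR 25.25 ms, 9 deg MTw at
    TR 29.25 ms, eight echoes 2.39..18.91 ms in steps of 2.36 ms."""
    te8 = _echo_train(2.39, 2.36, 8)
    return AcquisitionProtocol(
        weightings={
            "PDw": WeightingProtocol(5.0, 25.25, te8),
            "T1w": WeightingProtocol(29.0, 25.25, te8),
            "MTw": WeightingProtocol(9.0, 29.25, te8, mt_pulse=True),
        },
        cohort_id=1,
        name="cohort1",
    )


def cohort2_protocol() -> AcquisitionProtocol:
    """Second scanner preset: 6/21 deg PDw/T1w and 6 deg MTw, all at TR 25 ms;
    eight echoes 2.34..18.44 ms in steps of 2.30 ms, only six for MTw."""
    te8 = _echo_train(2.34, 2.30, 8)
    return AcquisitionProtocol(
        weightings={
            "PDw": WeightingProtocol(6.0, 25.0, te8),
            "T1w": WeightingProtocol(21.0, 25.0, te8),
            "MTw": WeightingProtocol(6.0, 25.0, te8[:6], mt_pulse=True),
        },
        cohort_id=2,
        name="cohort2",
    )


_PRESETS = {"cohort1": cohort1_protocol, "cohort2": cohort2_protocol}


def get_protocol(name: str | int) -> AcquisitionProtocol:
    """Look up a protocol preset by name (``cohort1``/``cohort2``) or id."""
    if isinstance(name, int):
        name = f"cohort{name}"
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown protocol preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
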