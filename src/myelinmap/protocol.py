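"""MP2RAGE acquisition protocol description.

An MP2RAGE cycle is: adiabatic inversion -> delay -> RAGE block 1 (n_gre
low-flip excitations) -> delay -> RAGE block 2 -> recovery delay, repeated
until steady state.  Each block samples one image; the inversion times TI1
and TI2 refer to the k-space-center excitation of the respective block.
All times are stored in seconds; protocol files use milliseconds (the
notation conventional on scanner consoles) unless told otherwise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml


class ProtocolError(ValueError):
    """Raised when timing or flip-angle parameters are unphysical."""


@dataclass(frozen=True)
class ProtocolParameters:
    """Timing and flip-angle description of one MP2RAGE acquisition.

    Parameters
    ----------
    tr_cycle:
        Duration of the full MP2RAGE cycle (inversion to inversion), s.
    ti1, ti2:
        Inversion times of the two image blocks, defined from the
        inversion pulse to the k-space-center excitation, s.
    tr_gre:
        Echo spacing between successive excitations inside a block, s.
    alpha1, alpha2:
        Nominal excitation flip angles of the two blocks, degrees.
    n_gre:
        Number of excitations per RAGE block.
    center_index:
        0-based index of the k-space-center excitation within a block
        (linear phase-encode ordering puts it near ``n_gre // 2``).
    inv_efficiency:
        Fraction of longitudinal magnetization inverted by the
        preparation pulse; 1 is a perfect inversion, 0 leaves the
        magnetization untouched.
    """

    tr_cycle: float = 5.0
    ti1: float = 0.7
    ti2: float = 2.5
    tr_gre: float = 0.0071
    alpha1: float = 4.0
    alpha2: float = 5.0
    n_gre: int = 59
    center_index: int = 29
    inv_efficiency: float = 0.96

    def __post_init__(self) -> None:
        if not (0 < self.ti1 < self.ti2 < self.tr_cycle):
            raise ProtocolError(
                f"need 0 < ti1 < ti2 < tr_cycle, got {self.ti1}, {self.ti2}, {self.tr_cycle}"
            )
        if self.tr_gre <= 0:
            raise ProtocolError("tr_gre must be positive")
        if not (0 < self.alpha1 < 90 and 0 < self.alpha2 < 90):
            raise ProtocolError("flip angles must lie in (0, 90) degrees")
        if not (0 <= self.center_index < self.n_gre):
            raise ProtocolError("center_index must lie in [0, n_gre)")
        if not (0.0 <= self.inv_efficiency <= 1.0):
            raise ProtocolError("inv_efficiency must lie in [0, 1]")
        for name, gap in (("TA", self.ta), ("TB", self.tb), ("TC", self.tc)):
            if gap < 0:
                raise ProtocolError(
                    f"negative inter-block gap {name}={gap:.4f} s; "
                    "timing parameters are inconsistent"
                )

    @property
    def ta(self) -> float:
        """Delay from inversion pulse to the first excitation of block 1, s."""
        return self.ti1 - self.center_index * self.tr_gre

    @property
    def tb(self) -> float:
        """Free-relaxation gap between the two RAGE blocks, s."""
        return self.ti2 - self.ti1 - self.n_gre * self.tr_gre

    @property
    def tc(self) -> float:
        """Recovery gap after block 2 until the next inversion, s."""
        return self.tr_cycle - self.ti2 - (self.n_gre - self.center_index) * self.tr_gre

    def fingerprint(self, b1_scale: float = 1.0) -> str:
        """Short stable hash of the protocol (and a B1 scale) for provenance."""
        payload = repr(sorted(asdict(self).items())) + f"|b1={float(b1_scale)!r}"
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_updates(self, **kwargs) -> "ProtocolParameters":
        return replace(self, **kwargs)


#: Protocol used throughout: 3-T MP2RAGE, TR 5000 ms, TI 700/2500 ms,
#: 4°/5° flips, 7.1 ms echo spacing, 59 excitations per block
#: (176 partitions at threefold parallel acceleration).
STUDY_PROTOCOL = ProtocolParameters()

_TIME_FIELDS = ("tr_cycle", "ti1", "ti2", "tr_gre")


def load_protocol(path: str | Path, units: str = "ms") -> ProtocolParameters:
    """Read a flat key-value protocol file.

    ``units`` selects the time dialect of the file: ``"ms"`` (default,
    matching console notation) or ``"s"``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    units = str(raw.pop("units", units))
    if units not in ("ms", "s"):
        raise ProtocolError(f"unknown time units dialect {units!r}")
    scale = 1e-3 if units == "ms" else 1.0
    kwargs = {}
    for key, value in raw.items():
        if key in _TIME_FIELDS:
            kwargs[key] = float(value) * scale
        elif key in ("n_gre", "center_index"):
            kwargs[key] = int(value)
        elif key in ("alpha1", "alpha2", "inv_efficiency"):
            kwargs[key] = float(value)
        else:
            raise ProtocolError(f"unknown protocol key {key!r}")
    return ProtocolParameters(**kwargs)


def save_protocol(protocol: ProtocolParameters, path: str | Path, units: str = "ms") -> None:
    """Write a protocol file in the requested time dialect."""
    if units not in ("ms", "s"):
        raise ProtocolError(f"unknown time units dialect {units!r}")
    scale = 1e3 if units == "ms" else 1.0
    data: dict = {"units": units}
    for key, value in asdict(protocol).items():
        data[key] = round(value * scale, 9) if key in _TIME_FIELDS else value
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
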