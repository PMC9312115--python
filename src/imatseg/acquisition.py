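"""Acquisition protocol metadata and the multi-echo image container.

A multi-echo spin-echo (MESE) scan acquires one magnitude image per echo
time TE_k = k * echo_spacing.  Everything downstream (dictionary simulation,
T2/PD fitting) is keyed to the :class:`Protocol` that produced the series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class Protocol:
    """MESE acquisition parameters.

    Defaults follow a standard 3T lower-limb protocol:
    TR/TE = 1479/8.7 ms, 17 echoes, 128x128 matrix.
    """

    echo_spacing: float = 8.7
    n_echoes: int = 17
    repetition_time: float = 1479.0
    excitation_flip: float = 90.0
    refocusing_flip: float = 180.0
    matrix_size: int = 128

    def __post_init__(self) -> None:
        if self.echo_spacing <= 0:
            raise ValueError("echo_spacing must be positive")
        if self.n_echoes < 2:
            raise ValueError("n_echoes must be >= 2")
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be positive")

    @property
    def echo_times(self) -> np.ndarray:
        """TE_k = k * echo_spacing for k = 1..n_echoes, in ms."""
        return self.echo_spacing * np.arange(1, self.n_echoes + 1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(**d)


@dataclass
class EchoSeries:
    """One slice's stack of echo images, shape (H, W, n_echoes)."""

    data: np.ndarray
    protocol: Protocol = field(default_factory=Protocol)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("EchoSeries data must be (H, W, n_echoes)")
        if self.data.shape[2] != self.protocol.n_echoes:
            raise ValueError(
                f"series has {self.data.shape[2]} echoes but protocol "
                f"declares {self.protocol.n_echoes}"
            )

    @property
    def shape(self) -> tuple:
        return self.data.shape[:2]

    def save(self, path: str | Path) -> None:
        """Write to NPZ (``.npz``) or NIfTI (``.nii``/``.nii.gz``)."""
        path = Path(path)
        if path.suffix == ".npz":
            proto = self.protocol
            np.savez_compressed(
                path,
                data=self.data,
                protocol=np.array(
                    [proto.echo_spacing, proto.n_echoes, proto.repetition_time,
                     proto.excitation_flip, proto.refocusing_flip,
                     proto.matrix_size]
                ),
            )
        else:
            import nibabel as nib

            img = nib.Nifti1Image(self.data.astype(np.float32), np.eye(4))
            img.header["descrip"] = (
                f"esp={self.protocol.echo_spacing};ne={self.protocol.n_echoes}"
            )
            nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path, protocol: Protocol | None = None) -> "EchoSeries":
        path = Path(path)
        if path.suffix == ".npz":
            with np.load(path) as f:
                data = f["data"]
                p = f["protocol"]
            proto = Protocol(
                echo_spacing=float(p[0]), n_echoes=int(p[1]),
                repetition_time=float(p[2]), excitation_flip=float(p[3]),
                refocusing_flip=float(p[4]), matrix_size=int(p[5]),
            )
            return cls(data=data, protocol=proto)
        import nibabel as nib

        data = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
        return cls(data=data, protocol=protocol or Protocol(n_echoes=data.shape[2]))
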