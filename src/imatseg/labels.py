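"""Tissue code table and the per-pixel label map shared across the pipeline.

Codes partition a slice into background, subcutaneous fat (SAT), viable
muscle, intramuscular fat (IMAT), cortical bone, and bone marrow.  The
muscle region -- everything inside the fascia lata except bone -- is the
union of the viable and IMAT codes; it is the domain of the stage-2
clustering and of the IMAT-fraction biomarker.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

BACKGROUND = 0
SAT = 1
VIABLE = 2
IMAT = 3
BONE = 4
MARROW = 5

CODE_NAMES = {
    BACKGROUND: "background",
    SAT: "subcutaneous fat",
    VIABLE: "viable muscle",
    IMAT: "IMAT",
    BONE: "bone",
    MARROW: "bone marrow",
}


@dataclass
class TissueLabelMap:
    """Per-pixel tissue codes plus the binary muscle-region mask.

    ``labels`` uses the module-level code table; inside ``muscle_mask`` every
    pixel is VIABLE or IMAT, outside it labels are BACKGROUND (or other
    non-muscle codes when the map carries full anatomy).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")

    @property
    def muscle_mask(self) -> np.ndarray:
        return (self.labels == VIABLE) | (self.labels == IMAT)

    @property
    def viable_mask(self) -> np.ndarray:
        return self.labels == VIABLE

    @property
    def imat_mask(self) -> np.ndarray:
        return self.labels == IMAT

    def save(self, path: str | Path) -> None:
        np.savez_compressed(Path(path), labels=self.labels)

    @classmethod
    def load(cls, path: str | Path) -> "TissueLabelMap":
        with np.load(Path(path)) as f:
            return cls(labels=f["labels"])
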