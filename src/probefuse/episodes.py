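"""The N-way K-shot episode container shared across the pipeline."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class Episode:
    """One few-shot task: a labeled support set and a held-out query set.

    Labels are integers 0..N-1. The support set contains every class exactly
    K times; query labels are drawn from the same classes. Images are
    [n, channels, H, W] float arrays.
    """

    support_images: np.ndarray
    support_labels: np.ndarray
    query_images: np.ndarray
    query_labels: np.ndarray

    def __post_init__(self):
        self.support_images = np.asarray(self.support_images, dtype=np.float64)
        self.query_images = np.asarray(self.query_images, dtype=np.float64)
        self.support_labels = np.asarray(self.support_labels, dtype=np.intp)
        self.query_labels = np.asarray(self.query_labels, dtype=np.intp)
        if len(self.support_images) != len(self.support_labels):
            raise ValueError("support images/labels length mismatch")
        if len(self.query_images) != len(self.query_labels):
            raise ValueError("query images/labels length mismatch")
        if len(self.support_labels) == 0:
            raise ValueError("support set is empty")
        classes, counts = np.unique(self.support_labels, return_counts=True)
        if len(set(counts)) > 1:
            raise ValueError(
                f"support is not class-balanced: counts {dict(zip(classes, counts))}"
            )
        extra = set(np.unique(self.query_labels)) - set(classes)
        if extra:
            raise ValueError(f"query contains unseen classes {sorted(extra)}")
        missing = set(classes) - set(np.unique(self.query_labels))
        if missing:
            warnings.warn(
                f"classes {sorted(missing)} absent from the query set",
                stacklevel=2,
            )

    @property
    def n_way(self) -> int:
        return len(np.unique(self.support_labels))

    @property
    def k_shot(self) -> int:
        return len(self.support_labels) // self.n_way

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.support_labels)

    @property
    def support(self) -> tuple[np.ndarray, np.ndarray]:
        return self.support_images, self.support_labels

    @property
    def query(self) -> tuple[np.ndarray, np.ndarray]:
        return self.query_images, self.query_labels
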