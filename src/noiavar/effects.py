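"""Labelled genetic-effect estimates with their sampling (co)variance.

:class:`EffectEstimates` is the bridge between model fitting and variance
prediction: a vector of functional effect estimates (intercept first, then
the design columns of a :class:`~noiavar.design.ModelSpec`) together with the
full sampling covariance matrix of those estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EffectEstimates"]


@dataclass
class EffectEstimates:
    labels: tuple[str, ...]
    values: np.ndarray
    cov: np.ndarray | None = None
    trait: str = ""
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),):
            raise ValueError("values length does not match labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate effect labels")
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)
            k = len(self.labels)
            if self.cov.shape != (k, k):
                raise ValueError("covariance shape does not match labels")
            if not np.allclose(self.cov, self.cov.T, atol=1e-8):
                raise ValueError("covariance matrix is not symmetric")
        self._index = {l: i for i, l in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> float:
        return float(self.values[self._index[label]])

    def __contains__(self, label: str) -> bool:
        return label in self._index

    @property
    def mu(self) -> float:
        """Intercept (reference-genotype value); 0 if no ``mu`` label present."""
        return self["mu"] if "mu" in self else 0.0

    def aligned(self, labels) -> tuple[np.ndarray, np.ndarray]:
        """Effect vector and covariance aligned to ``labels``.

        Epistatic labels absent from the estimate set are treated as exactly
        zero with zero sampling (co)variance — the convention for locus pairs
        with no interaction measurements.  A missing intercept or main-effect
        label raises, since silence there is a mistake rather than a modelling
        assumption.
        """
        labels = list(labels)
        k = len(labels)
        b = np.zeros(k)
        S = np.zeros((k, k))
        present = []
        for out_i, lab in enumerate(labels):
            if lab in self._index:
                present.append((out_i, self._index[lab]))
            elif lab == "mu" or lab.startswith(("a:", "d:")):
                raise KeyError(f"effect {lab!r} missing from estimates")
        for out_i, src_i in present:
            b[out_i] = self.values[src_i]
        if self.cov is not None:
            for out_i, src_i in present:
                for out_j, src_j in present:
                    S[out_i, out_j] = self.cov[src_i, src_j]
        return b, S

    def standard_errors(self) -> np.ndarray:
        if self.cov is None:
            return np.full(len(self.labels), np.nan)
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table of label, estimate and standard error."""
        return pd.DataFrame(
            {"label": self.labels, "estimate": self.values, "se": self.standard_errors()}
        )

    def cov_frame(self) -> pd.DataFrame:
        if self.cov is None:
            raise ValueError("no covariance matrix attached")
        return pd.DataFrame(self.cov, index=self.labels, columns=self.labels)

    @classmethod
    def from_mapping(cls, mapping, cov=None, trait="", labels=None) -> "EffectEstimates":
        """Build from a {label: value} mapping; absent covariance defaults to None."""
        if labels is None:
            labels = tuple(mapping)
        values = np.array([mapping.get(l, 0.0) for l in labels], dtype=float)
        return cls(tuple(labels), values, cov, trait)

    def replace_values(self, values, cov=None) -> "EffectEstimates":
        return EffectEstimates(self.labels, values, cov, self.trait)
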