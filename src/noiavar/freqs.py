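"""Allele-frequency ensembles: uniform and U-shaped sampling, serialization.

Variance predictions are functions of donor-allele frequencies, so ensembles
of frequency sets are the independent variable of every population-level
summary.  Two samplers are provided: uniform on [0, 1], and the neutral-
theory U-shaped density ∝ 1/(p(1−p)) truncated to [ε, 1−ε], drawn by inverse
CDF (the truncated-logit transform).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FrequencyEnsemble", "sample_frequencies", "u_shaped_cdf"]


def u_shaped_cdf(p, eps: float) -> np.ndarray:
    """CDF of the truncated density ∝ 1/(p(1−p)) on [ε, 1−ε]."""
    p = np.asarray(p, dtype=float)
    lo = np.log(eps / (1 - eps))
    return (np.log(p / (1 - p)) - lo) / (-2 * lo)


@dataclass
class FrequencyEnsemble:
    """A list of frequency sets (rows) over named loci (columns)."""

    loci: tuple[str, ...]
    sets: np.ndarray  # (n_sets, n_loci)
    distribution: str = "uniform"
    seed: int | None = None
    eps: float = 0.01

    def __post_init__(self):
        self.loci = tuple(self.loci)
        self.sets = np.asarray(self.sets, dtype=float)
        if self.sets.ndim != 2 or self.sets.shape[1] != len(self.loci):
            raise ValueError("sets must be (n_sets, n_loci)")
        if np.any((self.sets < 0) | (self.sets > 1)):
            raise ValueError("frequencies must lie in [0, 1]")

    def __len__(self) -> int:
        return self.sets.shape[0]

    def __iter__(self):
        return iter(self.sets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sets, columns=self.loci)

    def write(self, path) -> None:
        """Write the sets as CSV plus a JSON sidecar with sampling metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.12g")
        meta = {"distribution": self.distribution, "seed": self.seed, "eps": self.eps}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def read(cls, path) -> "FrequencyEnsemble":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            loci=tuple(df.columns),
            sets=df.to_numpy(),
            distribution=meta.get("distribution", "external"),
            seed=meta.get("seed"),
            eps=meta.get("eps", 0.01),
        )


def sample_frequencies(
    distribution: str,
    n_sets: int,
    loci,
    seed: int,
    eps: float = 0.01,
) -> FrequencyEnsemble:
    """Draw ``n_sets`` independent frequency sets, one frequency per locus.

    ``distribution`` is ``"uniform"`` (U(0, 1)) or ``"u_shaped"`` (density
    ∝ 1/(p(1−p)) truncated to [ε, 1−ε]).  Frequencies are independent across
    loci and sets and reproducible given ``seed``.
    """
    if isinstance(loci, int):
        loci = tuple(f"L{i + 1}" for i in range(loci))
    loci = tuple(loci)
    if n_sets < 1 or len(loci) < 1:
        raise ValueError("need at least one set and one locus")
    rng = np.random.default_rng(seed)
    u = rng.random((n_sets, len(loci)))
    if distribution == "uniform":
        sets = u
    elif distribution == "u_shaped":
        if not 0.0 < eps < 0.5:
            raise ValueError("eps must lie in (0, 0.5)")
        # inverse of u_shaped_cdf: logit-linear interpolation between the bounds
        lo = np.log(eps / (1 - eps))
        z = lo * (1 - 2 * u)
        sets = 1.0 / (1.0 + np.exp(-z))
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return FrequencyEnsemble(
        loci=loci, sets=sets, distribution=distribution, seed=seed, eps=eps
    )
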