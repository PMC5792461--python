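"""Mechanistic model of MBD2-Fc capture of a mixed host/bacterial fragment pool.

An MBD2-Fc protein coupled to a paramagnetic bead binds double-stranded DNA
carrying methylated CpG dinucleotides. Vertebrate (host) DNA is densely
CpG-methylated while gut-bacterial DNA is essentially unmethylated, so
capture partitions a fecal DNA extract toward the host. Two features of the
chemistry matter for modeling: a fraction of *unmethylated* DNA is bound
nonspecifically, and repeating the capture on the bound output (serial
enrichment) compounds the separation.

The capture curve used here is a two-parameter saturating (Michaelis-type)
function of a fragment's methylated-CpG count ``m``::

    p(m) = p_bg + (p_max - p_bg) * m / (m + k_half)

``p_bg`` is the nonspecific background binding probability, ``p_max`` the
probability at saturating methylation density, and ``k_half`` the count at
half-saturation. Each fragment is retained as an independent Bernoulli
trial; closed-form expectations accompany the stochastic simulator so it
can be tested against them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HOST = "host"
BACTERIAL = "bacterial"


@dataclass(frozen=True)
class CaptureParams:
    """Parameters of the saturating capture curve plus the round count."""

    p_max: float = 0.8
    p_bg: float = 0.05
    k_half: float = 5.0
    rounds: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_bg <= self.p_max <= 1.0:
            raise ValueError("require 0 <= p_bg <= p_max <= 1")
        if self.k_half <= 0:
            raise ValueError("k_half must be positive")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass
class FragmentPool:
    """Fragments tagged with origin and methylated-CpG count.

    ``is_host`` is a boolean array; ``methyl_cpg`` the per-fragment count of
    methylated CpGs. Under the default community model bacterial fragments
    carry ``m = 0``.
    """

    is_host: np.ndarray
    methyl_cpg: np.ndarray
    depleted: bool = False

    def __post_init__(self) -> None:
        self.is_host = np.asarray(self.is_host, dtype=bool)
        self.methyl_cpg = np.asarray(self.methyl_cpg, dtype=np.int64)
        if self.is_host.shape != self.methyl_cpg.shape:
            raise ValueError("is_host and methyl_cpg must have equal length")
        if np.any(self.methyl_cpg < 0):
            raise ValueError("methyl_cpg counts must be nonnegative")

    def __len__(self) -> int:
        return self.is_host.size

    @property
    def n_host(self) -> int:
        return int(self.is_host.sum())

    @property
    def host_fraction(self) -> float:
        if len(self) == 0:
            return float("nan")
        return self.n_host / len(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "origin": np.where(self.is_host, HOST, BACTERIAL),
                "methyl_cpg_count": self.methyl_cpg,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FragmentPool":
        origin = frame["origin"].astype(str).to_numpy()
        bad = set(origin) - {HOST, BACTERIAL}
        if bad:
            raise ValueError(f"unknown fragment origins: {sorted(bad)}")
        return cls(origin == HOST, frame["methyl_cpg_count"].to_numpy())

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FragmentPool":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def capture_prob(m, params: CaptureParams):
    """Capture probability for methylated-CpG count ``m`` (scalar or array)."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("methyl-CpG counts must be nonnegative")
    p = params.p_bg + (params.p_max - params.p_bg) * m / (m + params.k_half)
    return float(p) if p.ndim == 0 else p


def enrich_round(pool: FragmentPool, params: CaptureParams, seed) -> FragmentPool:
    """One capture reaction: independent Bernoulli retention per fragment.

    An empty surviving pool is returned flagged ``depleted`` rather than
    raising, mirroring a failed capture.
    """
    if len(pool) == 0:
        raise ValueError("cannot enrich an empty pool")
    rng = np.random.default_rng(seed)
    p = capture_prob(pool.methyl_cpg, params)
    keep = rng.random(len(pool)) < p
    out = FragmentPool(pool.is_host[keep], pool.methyl_cpg[keep])
    out.depleted = len(out) == 0
    return out


def serial_enrich(pool: FragmentPool, params: CaptureParams, seed) -> FragmentPool:
    """Apply ``params.rounds`` sequential capture reactions to the pool."""
    rng = np.random.default_rng(seed)
    out = pool
    for _ in range(params.rounds):
        if out.depleted:
            return out
        out = enrich_round(out, params, rng)
    return out


def mean_capture_probs(pool: FragmentPool, params: CaptureParams) -> tuple[float, float]:
    """Realized mean capture probability for (host, bacterial) fragments."""
    p = capture_prob(pool.methyl_cpg, params)
    ep_host = float(p[pool.is_host].mean()) if pool.n_host else float("nan")
    n_bact = len(pool) - pool.n_host
    ep_bact = float(p[~pool.is_host].mean()) if n_bact else float("nan")
    return ep_host, ep_bact


def expected_post_fraction(f: float, ep_host: float, ep_bact: float) -> float:
    """Expected host fraction after one capture round (closed form).

    ``f' = f Ep_host / (f Ep_host + (1 - f) Ep_bact)``. Returns NaN when
    both origin-wise expectations vanish (depleted pool).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    num = f * ep_host
    den = num + (1.0 - f) * ep_bact
    if den == 0.0:
        return float("nan")
    return num / den


def serial_expected_fraction(f0: float, ep_host: float, ep_bact: float, rounds: int) -> float:
    """Iterate the one-round closed form ``rounds`` times.

    Assumes the origin-wise mean capture probabilities are stable across
    rounds (exact when methylation density is homogeneous within origin).
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    f = f0
    for _ in range(rounds):
        f = expected_post_fraction(f, ep_host, ep_bact)
        if np.isnan(f):
            return f
    return f


def post_fraction_se(pool: FragmentPool, params: CaptureParams) -> float:
    """Delta-method standard error of the post-round host-fraction estimate.

    With ``H``, ``B`` the captured host/bacterial counts and
    ``f' = H/(H+B)``, the Bernoulli capture variances propagate as
    ``Var(f') ~ (E[B]^2 Var H + E[H]^2 Var B) / (E[H]+E[B])^4``.
    """
    p = capture_prob(pool.methyl_cpg, params)
    ph, pb = p[pool.is_host], p[~pool.is_host]
    eh, eb = ph.sum(), pb.sum()
    vh = float((ph * (1 - ph)).sum())
    vb = float((pb * (1 - pb)).sum())
    total = eh + eb
    if total == 0:
        return float("nan")
    return float(np.sqrt(eb**2 * vh + eh**2 * vb) / total**2)


def enrichment_report(pre: FragmentPool, post: FragmentPool, params: CaptureParams) -> dict:
    """Pre/post host fractions, closed-form expectation and its SE."""
    ep_host, ep_bact = mean_capture_probs(pre, params)
    f_pre = pre.host_fraction
    expected = serial_expected_fraction(f_pre, ep_host, ep_bact, params.rounds)
    return {
        "n_pre": len(pre),
        "n_post": len(post),
        "pre_host_fraction": f_pre,
        "post_host_fraction": post.host_fraction,
        "expected_post_fraction": expected,
        "post_fraction_se": post_fraction_se(pre, params),
        "rounds": params.rounds,
        "depleted": post.depleted,
    }
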