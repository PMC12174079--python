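"""Dale-compliant block connectivity with a rank-1 structure on E->E.

Weights are non-negative throughout (entries in [0, 1]); excitation and
inhibition are carried by the reversal potentials of the synapse models, so
Dale's principle holds structurally.  The E->E block is J_EE =
clip(lambda*chi + P, 0, 1) with P = outer(m, n) the rank-1 part; the other
three blocks are Gamma-distributed random weights with their target means.

Because the rank-1 entries are comparable to the random weights, truncation
to [0, 1] raises the realized E->E mean above the nominal Gamma mean.  The
Gamma mean of chi is therefore calibrated (bisection) so that the realized
post-truncation block mean hits the requested target, which is the single
number that also drives the macroscopic model (p_XY = block mean of J).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .params import RngLike, as_rng

BLOCKS = ("EE", "EI", "IE", "II")

#: Default per-entry standard deviation of the connectivity vectors m and n.
#: The published "N(0, 0.2)" is read as variance 0.2 (see package docs).
DEFAULT_SIGMA_LR = float(np.sqrt(0.2))


@dataclass
class LowRankStructure:
    """Rank-1 connectivity component P = outer(m, n).

    ``m`` is the right (output/readout) vector, ``n`` the left (input) vector.
    """

    m: np.ndarray
    n: np.ndarray
    sigma_lr: float

    @property
    def P(self) -> np.ndarray:
        return np.outer(self.m, self.n)


@dataclass
class ConnectivityConfig:
    """Targets and sampling settings for the four connectivity blocks."""

    mean_EE: float = 0.1
    mean_EI: float = 0.1   # I -> E block
    mean_IE: float = 0.1   # E -> I block
    mean_II: float = 0.2
    chi_sd: float = 0.1
    lam: float = 1.0       # scale of the random part (lambda)
    sigma_lr: float = DEFAULT_SIGMA_LR
    calibrate_ee_mean: bool = True

    def __post_init__(self) -> None:
        for b in BLOCKS:
            v = getattr(self, f"mean_{b}")
            if not (0.0 < v < 1.0):
                raise ValueError(f"mean_{b} must lie in (0, 1), got {v}")
        if self.chi_sd <= 0:
            raise ValueError("chi_sd must be > 0")
        if self.sigma_lr <= 0:
            raise ValueError("sigma_lr must be > 0")

    def block_mean(self, block: str) -> float:
        return getattr(self, f"mean_{block}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ConnectivitySet:
    """The four weight matrices plus the embedded rank-1 structure.

    ``J_EE`` is N_E x N_E, ``J_EI`` is N_E x N_I (inhibitory -> excitatory),
    ``J_IE`` is N_I x N_E, ``J_II`` is N_I x N_I.  J[i, j] is the weight from
    presynaptic neuron j to postsynaptic neuron i.
    """

    J_EE: np.ndarray
    J_EI: np.ndarray
    J_IE: np.ndarray
    J_II: np.ndarray
    lowrank: LowRankStructure
    config: ConnectivityConfig

    def block(self, name: str) -> np.ndarray:
        if name not in BLOCKS:
            raise KeyError(f"unknown block {name!r}; expected one of {BLOCKS}")
        return getattr(self, f"J_{name}")

    def block_means(self) -> dict:
        return {b: float(self.block(b).mean()) for b in BLOCKS}

    @property
    def N_E(self) -> int:
        return self.J_EE.shape[0]

    @property
    def N_I(self) -> int:
        return self.J_II.shape[0]

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            J_EE=self.J_EE, J_EI=self.J_EI, J_IE=self.J_IE, J_II=self.J_II,
            m=self.lowrank.m, n=self.lowrank.n,
            sigma_lr=self.lowrank.sigma_lr,
            config=np.array([repr(self.config.to_dict())], dtype=object),
        )

    @classmethod
    def load_npz(cls, path) -> "ConnectivitySet":
        import ast
        with np.load(path, allow_pickle=True) as f:
            cfg = ConnectivityConfig(**ast.literal_eval(str(f["config"][0])))
            lr = LowRankStructure(m=f["m"], n=f["n"], sigma_lr=float(f["sigma_lr"]))
            return cls(J_EE=f["J_EE"], J_EI=f["J_EI"], J_IE=f["J_IE"],
                       J_II=f["J_II"], lowrank=lr, config=cfg)


def sample_lowrank(N_E: int, sigma_lr: float = DEFAULT_SIGMA_LR,
                   rng: RngLike = None) -> LowRankStructure:
    """Sample m_i, n_i ~ N(0, sigma_lr^2) i.i.d."""
    if N_E < 1:
        raise ValueError("N_E must be >= 1")
    if sigma_lr <= 0:
        raise ValueError("sigma_lr must be > 0")
    rng = as_rng(rng)
    m = rng.normal(0.0, sigma_lr, size=N_E)
    n = rng.normal(0.0, sigma_lr, size=N_E)
    return LowRankStructure(m=m, n=n, sigma_lr=sigma_lr)


def sample_gamma_block(rows: int, cols: int, mean: float, sd: float,
                       rng: RngLike = None) -> np.ndarray:
    """Gamma weights with given mean and sd (moment matching), clipped to [0,1].

    shape k = (mean/sd)^2, scale theta = sd^2/mean, so k*theta = mean and
    k*theta^2 = sd^2.
    """
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if sd <= 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    rng = as_rng(rng)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return np.clip(rng.gamma(shape, scale, size=(rows, cols)), 0.0, 1.0)


def _calibrated_ee_block(P: np.ndarray, target: float, sd: float, lam: float,
                         rng: np.random.Generator, tol: float = 5e-4,
                         max_iter: int = 24) -> np.ndarray:
    """Bisection on the Gamma mean of chi so mean(clip(lam*chi + P, 0, 1)) == target.

    The realized mean is monotone in the Gamma mean; each evaluation redraws
    chi from a child generator, so the residual Monte-Carlo error is
    O(sd/sqrt(N_E^2)), far below ``tol`` for the network sizes used here.
    """
    seeds = rng.spawn(max_iter + 1)
    lo, hi = 1e-4, max(target, 2e-4)
    mu = target
    for it in range(max_iter):
        mu = 0.5 * (lo + hi)
        chi = seeds[it].gamma((mu / sd) ** 2, sd * sd / mu, size=P.shape)
        realized = np.clip(lam * chi + P, 0.0, 1.0).mean()
        if abs(realized - target) < tol:
            break
        if realized > target:
            hi = mu
        else:
            lo = mu
    chi = seeds[-1].gamma((mu / sd) ** 2, sd * sd / mu, size=P.shape)
    return np.clip(lam * chi + P, 0.0, 1.0)


def assemble_connectivity(cfg: ConnectivityConfig, N_E: int, N_I: int,
                          rng: RngLike = None,
                          lowrank: Optional[LowRankStructure] = None) -> ConnectivitySet:
    """Build the full Dale-compliant connectivity.

    The rank-1 part is applied exclusively to the E->E block; the EI, IE and
    II blocks are Gamma-only with means at their targets.  Truncation to
    [0, 1] is applied after summing lam*chi + P.
    """
    rng = as_rng(rng)
    if lowrank is None:
        lowrank = sample_lowrank(N_E, cfg.sigma_lr, rng)
    P = lowrank.P
    if cfg.calibrate_ee_mean:
        J_EE = _calibrated_ee_block(P, cfg.mean_EE, cfg.chi_sd, cfg.lam, rng)
    else:
        chi = rng.gamma((cfg.mean_EE / cfg.chi_sd) ** 2,
                        cfg.chi_sd ** 2 / cfg.mean_EE, size=(N_E, N_E))
        J_EE = np.clip(cfg.lam * chi + P, 0.0, 1.0)
    J_EI = sample_gamma_block(N_E, N_I, cfg.mean_EI, cfg.chi_sd, rng)
    J_IE = sample_gamma_block(N_I, N_E, cfg.mean_IE, cfg.chi_sd, rng)
    J_II = sample_gamma_block(N_I, N_I, cfg.mean_II, cfg.chi_sd, rng)
    return ConnectivitySet(J_EE=J_EE, J_EI=J_EI, J_IE=J_IE, J_II=J_II,
                           lowrank=lowrank, config=cfg)


def make_go_input(lr: LowRankStructure) -> np.ndarray:
    """The Go stimulus is the left connectivity vector itself: I_go = n."""
    return lr.n.copy()


def make_nogo_input(lr: LowRankStructure, rng: RngLike = None) -> np.ndarray:
    """Gaussian stimulus orthogonal to n with the norm of the raw draw.

    A vector with the same per-entry statistics as n is sampled, its
    projection onto n removed (one Gram-Schmidt step) and the result rescaled
    to the pre-projection Euclidean norm.
    """
    n = lr.n
    nn = float(n @ n)
    if nn == 0.0:
        raise ValueError("n is the zero vector; cannot orthogonalize")
    rng = as_rng(rng)
    raw = rng.normal(0.0, lr.sigma_lr, size=n.shape[0])
    proj = raw - (raw @ n) / nn * n
    norm_proj = np.linalg.norm(proj)
    if norm_proj == 0.0:
        raise ValueError("degenerate draw: projection left a zero vector")
    return proj * (np.linalg.norm(raw) / norm_proj)


def readout_vector(lr: LowRankStructure) -> np.ndarray:
    """The readout vector equals the right connectivity vector: W_out = m."""
    return lr.m.copy()


def ablate_blocks(conn: ConnectivitySet, blocks_to_zero) -> ConnectivitySet:
    """Return a copy of the connectivity with the named blocks zeroed."""
    blocks_to_zero = set(blocks_to_zero)
    unknown = blocks_to_zero - set(BLOCKS)
    if unknown:
        raise KeyError(f"unknown block(s) {sorted(unknown)}; expected subset of {BLOCKS}")
    new = {f"J_{b}": (np.zeros_like(conn.block(b)) if b in blocks_to_zero
                      else conn.block(b).copy())
           for b in BLOCKS}
    return ConnectivitySet(lowrank=conn.lowrank, config=conn.config, **new)
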