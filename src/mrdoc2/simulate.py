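"""Twin-pair data generation: exact-moment and stochastic modes.

Exact mode hands the model-implied population moments to the fitter as if
they were sample moments ("exact data simulation"): ML estimates of the
generating model then equal the true parameter values and a constrained
fit's discrepancy equals the exact LRT noncentrality parameter — no
Monte-Carlo noise, no raw data.

Stochastic mode draws real pairs from the zygosity-specific multivariate
normal; MZ co-twins receive literally identical polygenic-score values,
realised by sampling the shared exogenous factors once per pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import GroupMoments, MomentData
from .model import implied_covariance
from .parameters import DZ, MZ, ParamVector, Zygosity

__all__ = [
    "StudyDesign",
    "ReliabilitySpec",
    "TWIN_COLUMNS",
    "exact_moments",
    "sample_pairs",
    "inject_measurement_error",
    "attenuated_exact_moments",
]

#: Column schema of a wide-format twin table (one row per pair).
TWIN_COLUMNS = (
    "pair_id", "zygosity",
    "ph1_t1", "ph2_t1", "ps1_t1", "ps2_t1",
    "ph1_t2", "ph2_t2", "ps1_t2", "ps2_t2",
)

_PH_COLUMNS = ("ph1_t1", "ph2_t1", "ph1_t2", "ph2_t2")


@dataclass(frozen=True)
class StudyDesign:
    """Sample sizes, seed and generation mode of a simulated twin study."""

    n_mz: int = 1000
    n_dz: int = 1000
    seed: int = 0
    mode: str = "exact"

    def __post_init__(self) -> None:
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("pair counts must be nonnegative")
        if self.mode not in ("exact", "stochastic"):
            raise ValueError(f"mode must be 'exact' or 'stochastic', got {self.mode!r}")


@dataclass(frozen=True)
class ReliabilitySpec:
    """Phenotypic reliabilities: share of observed variance that is true score."""

    rel_ph1: float = 1.0
    rel_ph2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rel_ph1", "rel_ph2"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def exact_moments(theta: ParamVector, design: StudyDesign) -> MomentData:
    """Population implied moments presented as sample moments.

    Equivalent to simulating data whose sample moments match the population
    ones exactly, but skips data generation entirely.
    """
    if design.mode != "exact":
        raise ValueError("exact_moments requires design.mode == 'exact'")
    if design.n_mz == 0 and design.n_dz == 0:
        raise ValueError("design has no twin pairs: no information to fit")
    mz = dz = None
    if design.n_mz > 0:
        mz = GroupMoments(implied_covariance(theta, MZ), np.zeros(8), design.n_mz)
    if design.n_dz > 0:
        dz = GroupMoments(implied_covariance(theta, DZ), np.zeros(8), design.n_dz)
    return MomentData(mz=mz, dz=dz)


def _pair_transform(theta: ParamVector, zyg: Zygosity) -> np.ndarray:
    """Matrix M with cov(M z) equal to the implied pair covariance, z std-normal.

    Built from the eigendecomposition of the implied covariance with
    eigenvalues clipped at zero: the MZ covariance is structurally singular
    (shared polygenic scores), which a Cholesky factor cannot handle.
    """
    sigma = implied_covariance(theta, zyg)
    w, v = np.linalg.eigh(sigma)
    if w[0] < -1e-8:
        raise ValueError(
            f"implied {zyg.label} covariance is not positive semidefinite"
        )
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def sample_pairs(theta: ParamVector, design: StudyDesign) -> pd.DataFrame:
    """Draw twin pairs from the zygosity-specific multivariate normal.

    Returns a wide table with :data:`TWIN_COLUMNS`; reproducible under the
    design's seed.
    """
    if design.mode != "stochastic":
        raise ValueError("sample_pairs requires design.mode == 'stochastic'")
    if design.n_mz == 0 and design.n_dz == 0:
        raise ValueError("design has no twin pairs")
    rng = np.random.default_rng(design.seed)
    frames = []
    offset = 0
    for zyg, n in ((MZ, design.n_mz), (DZ, design.n_dz)):
        if n == 0:
            continue
        m = _pair_transform(theta, zyg)
        data = rng.standard_normal((n, 8)) @ m.T
        frame = pd.DataFrame(data, columns=TWIN_COLUMNS[2:])
        frame.insert(0, "zygosity", zyg.label)
        frame.insert(0, "pair_id", np.arange(offset, offset + n))
        offset += n
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def inject_measurement_error(
    table: pd.DataFrame, rel: ReliabilitySpec, seed: int
) -> pd.DataFrame:
    """Add unmodelled measurement error to the phenotype columns.

    Each phenotype column x gains independent normal noise scaled so that
    the reliability of the noisy column — the share of its variance that is
    true score — equals the requested value:

        x* = x + sqrt(Var(x) * (1 - rel) / rel) * eps.

    The true score is left on its original scale (no shrinkage), so the
    error is absorbed entirely by the unique-environment part of the model;
    polygenic-score columns are untouched.  ``rel = 1`` returns the input
    unchanged.
    """
    out = table.copy()
    if rel.rel_ph1 == 1.0 and rel.rel_ph2 == 1.0:
        return out
    rng = np.random.default_rng(seed)
    rels = {"ph1": rel.rel_ph1, "ph2": rel.rel_ph2}
    for col in _PH_COLUMNS:
        r = rels[col[:3]]
        if r == 1.0:
            continue
        x = out[col].to_numpy(dtype=float)
        noise_sd = np.sqrt(np.var(x, ddof=1) * (1.0 - r) / r)
        out[col] = x + noise_sd * rng.standard_normal(x.size)
    return out


def attenuated_exact_moments(
    theta: ParamVector, rel: ReliabilitySpec, design: StudyDesign
) -> MomentData:
    """Exact population moments of phenotypes observed with measurement error.

    Adds the reliability-implied error variance, Var(Ph)*(1-rel)/rel, to the
    phenotype diagonal of each implied covariance.  This is the n -> inf
    limit of :func:`inject_measurement_error` and lets bias and power under
    unmodelled error be computed without Monte-Carlo noise.
    """
    base = exact_moments(theta, design)
    rels = {"ph1": rel.rel_ph1, "ph2": rel.rel_ph2}
    # diagonal positions of ph1_t1, ph2_t1, ph1_t2, ph2_t2 in VARIABLES order
    idx = {0: "ph1", 1: "ph2", 4: "ph1", 5: "ph2"}

    def attenuate(grp: GroupMoments | None) -> GroupMoments | None:
        if grp is None:
            return None
        cov = grp.covariance.copy()
        for i, key in idx.items():
            r = rels[key]
            cov[i, i] += cov[i, i] * (1.0 - r) / r
        return GroupMoments(cov, grp.mean, grp.n_pairs)

    return MomentData(mz=attenuate(base.mz), dz=attenuate(base.dz))
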