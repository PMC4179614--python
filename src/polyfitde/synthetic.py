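"""Two-condition overdispersed count simulator with known truth labels.

Counts for gene i in replicate j of the control condition are drawn from an
overdispersed count family with mean ``Lambda_j * mu_i`` and overdispersion
``phi_i`` (``Var = m + phi m^2``).  Treatment replicates use mean
``theta_i * Lambda'_j * mu_i`` with an independent second set of library
factors ``Lambda'``.  Library factors model sequencing-depth variation:
``log2 Lambda ~ N(0, 1)``, shared across genes within a replicate.

A configured fraction of genes is regulated, split into up- and
down-regulated subsets of equal size with factors ``theta = 2 + Exp(1)`` and
``theta = 1 / (2 + Exp(1))`` respectively, so every regulated gene changes by
at least a factor of 2.

Two count families are provided: negative binomial, and Poisson-inverse-
Gaussian (a Poisson-Tweedie family closer to Poisson in shape), with matched
mean and variance: ``Y | Z ~ Poisson(m Z)`` with Z inverse-Gaussian of mean 1
and variance phi gives ``Var(Y) = m + phi m^2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .count_model import CountMatrix

logger = logging.getLogger(__name__)

FAMILIES = ("nb", "pig")


@dataclass(frozen=True)
class GeneParamTable:
    """Per-gene simulation parameters: mean ``mu`` (> 0) and overdispersion ``phi`` (>= 0)."""

    table: pd.DataFrame  # columns: gene, mu, phi

    def __post_init__(self) -> None:
        required = ["gene", "mu", "phi"]
        if list(self.table.columns[:3]) != required:
            raise ValueError(f"parameter table must have columns {required}")
        mu = self.table["mu"].to_numpy(dtype=float)
        phi = self.table["phi"].to_numpy(dtype=float)
        for name, arr in (("mu", mu), ("phi", phi)):
            bad = ~np.isfinite(arr)
            if bad.any():
                row = int(np.argmax(bad))
                raise ValueError(
                    f"non-finite {name} for gene {self.table['gene'].iloc[row]!r} (row {row + 2})"
                )
        if (mu <= 0).any():
            row = int(np.argmax(mu <= 0))
            raise ValueError(
                f"mu must be > 0; gene {self.table['gene'].iloc[row]!r} (row {row + 2})"
            )
        if (phi < 0).any():
            row = int(np.argmax(phi < 0))
            raise ValueError(
                f"phi must be >= 0; gene {self.table['gene'].iloc[row]!r} (row {row + 2})"
            )

    @property
    def gene_ids(self) -> np.ndarray:
        return self.table["gene"].to_numpy()

    @property
    def mu(self) -> np.ndarray:
        return self.table["mu"].to_numpy(dtype=float)

    @property
    def phi(self) -> np.ndarray:
        return self.table["phi"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    def rescaled(self, target_total: float) -> "GeneParamTable":
        """Scale the means so they sum exactly to ``target_total``."""
        out = self.table.copy()
        out["mu"] = out["mu"] * (target_total / out["mu"].sum())
        return GeneParamTable(out)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_arrays(cls, mu, phi, gene_ids=None) -> "GeneParamTable":
        mu = np.asarray(mu, dtype=float)
        if gene_ids is None:
            gene_ids = [f"g{i + 1:06d}" for i in range(len(mu))]
        return cls(pd.DataFrame({"gene": gene_ids, "mu": mu, "phi": np.asarray(phi, float)}))

    @classmethod
    def from_tsv(cls, path) -> "GeneParamTable":
        raw = pd.read_csv(path, sep="\t")
        for col in ("mu", "phi"):
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            if bad.any():
                row = int(np.argmax(bad.to_numpy()))
                raise ValueError(f"malformed {col} value in line {row + 2} of {path}")
            raw[col] = coerced
        return cls(raw)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a transcriptome-scale two-class experiment: 46,446 genes
    whose means sum to 1e7 counts, 4 replicates per condition, 15% of genes
    regulated.
    """

    t: int = 46_446
    n: int = 4
    frac_de: float = 0.15
    family: str = "nb"
    seed: int = 0
    target_total: float | None = 1.0e7

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.t < 1 or self.n < 1:
            raise ValueError("t and n must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-gene regulation factors, DE labels and the library factors used."""

    gene_ids: np.ndarray
    theta: np.ndarray
    is_de: np.ndarray
    lambda_contr: np.ndarray
    lambda_treat: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.gene_ids, "theta": self.theta, "is_de": self.is_de})


def sample_library_factors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Library scaling factors Lambda_j = 2**Z_j with Z iid standard normal."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0 ** rng.standard_normal(n)


def regulated_count(t: int, frac_de: float) -> int:
    """Number of regulated genes: round(frac_de * t) half-up, forced even."""
    m = int(np.floor(frac_de * t + 0.5))
    if m % 2:
        m -= 1
    return m


def sample_regulation(
    t: int, frac_de: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Regulation factors theta and DE labels for ``t`` genes.

    A random even-sized subset is halved into up-regulated genes
    (theta = 2 + Exp(1), so theta >= 2) and down-regulated genes
    (theta = 1 / (2 + Exp(1)), so theta <= 1/2); all others keep theta = 1.
    """
    if not 0.0 <= frac_de <= 1.0:
        raise ValueError("frac_de must lie in [0, 1]")
    m = regulated_count(t, frac_de)
    if frac_de > 0 and m < 2:
        raise ValueError("frac_de * t must be at least 2 when frac_de > 0")
    theta = np.ones(t)
    if m:
        chosen = rng.choice(t, size=m, replace=False)
        up, down = chosen[: m // 2], chosen[m // 2 :]
        theta[up] = 2.0 + rng.exponential(1.0, size=len(up))
        theta[down] = 1.0 / (2.0 + rng.exponential(1.0, size=len(down)))
    return theta, theta != 1.0


def draw_counts(
    mean: np.ndarray, phi: np.ndarray, family: str, rng: np.random.Generator
) -> np.ndarray:
    """Draw a genes x replicates count matrix with ``Var = m + phi m^2``.

    ``mean`` is genes x replicates; ``phi`` per gene.  Genes with phi = 0
    fall back to Poisson in both families.
    """
    mean = np.atleast_2d(np.asarray(mean, dtype=float))
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(mean)) or not np.all(np.isfinite(phi)):
        bad = np.argmax(~np.isfinite(mean).all(axis=1) | ~np.isfinite(phi))
        raise ValueError(f"non-finite simulation parameters for gene index {bad}")
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    out = np.empty(mean.shape, dtype=np.int64)
    od = phi > 0
    if family == "nb":
        if od.any():
            r = 1.0 / phi[od]
            m = mean[od]
            out[od] = rng.negative_binomial(r[:, None], r[:, None] / (r[:, None] + m))
    else:  # Poisson-inverse-Gaussian: Poisson mixed over IG(mean 1, var phi)
        if od.any():
            shape = (int(od.sum()), mean.shape[1])
            z = rng.wald(1.0, np.broadcast_to(1.0 / phi[od, None], shape))
            out[od] = rng.poisson(mean[od] * z)
    if (~od).any():
        out[~od] = rng.poisson(mean[~od])
    return out


def simulate_counts(
    params: GeneParamTable, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CountMatrix, SyntheticTruth]:
    """Generate one two-condition dataset with truth labels.

    Control and treatment conditions each draw their own independent set of
    library factors.  If ``cfg.target_total`` is set the means are first
    rescaled so they sum to it exactly.
    """
    if len(params) != cfg.t:
        raise ValueError(f"parameter table has {len(params)} genes, config expects {cfg.t}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.target_total is not None:
        params = params.rescaled(cfg.target_total)
    mu, phi = params.mu, params.phi
    lam_contr = sample_library_factors(cfg.n, rng)
    lam_treat = sample_library_factors(cfg.n, rng)
    theta, is_de = sample_regulation(cfg.t, cfg.frac_de, rng)
    mean_contr = mu[:, None] * lam_contr[None, :]
    mean_treat = (theta * mu)[:, None] * lam_treat[None, :]
    k_contr = draw_counts(mean_contr, phi, cfg.family, rng)
    k_treat = draw_counts(mean_treat, phi, cfg.family, rng)
    cols = [f"contr_{j + 1}" for j in range(cfg.n)] + [f"treat_{j + 1}" for j in range(cfg.n)]
    counts = pd.DataFrame(
        np.hstack([k_contr, k_treat]), index=pd.Index(params.gene_ids, name="gene"),
        columns=cols,
    )
    conditions = pd.Series(
        ["control"] * cfg.n + ["treatment"] * cfg.n, index=counts.columns, name="condition"
    )
    truth = SyntheticTruth(
        gene_ids=params.gene_ids,
        theta=theta,
        is_de=is_de,
        lambda_contr=lam_contr,
        lambda_treat=lam_treat,
    )
    logger.info(
        "simulated %d genes x 2x%d replicates (%s), %d regulated",
        cfg.t, cfg.n, cfg.family, int(is_de.sum()),
    )
    return CountMatrix(counts, conditions), truth


def sample_params(
    t: int,
    rng: np.random.Generator,
    target_total: float = 1.0e7,
    mean_sdlog: float = 2.0,
    phi_shape: float = 1.2,
    phi_scale: float = 0.15,
) -> GeneParamTable:
    """Meta-sampler for gene parameters when no estimated table is supplied.

    Synthetic stand-in for a table of per-gene maximum-likelihood NB estimates
    from deep human RNA-seq data: log-normal means spanning several orders of
    magnitude (sdlog 2 in natural log), rescaled to sum to ``target_total``,
    and gamma-distributed overdispersions with mean ``phi_shape * phi_scale``
    (default 0.18, typical of bulk human replicates).
    """
    mu = rng.lognormal(0.0, mean_sdlog, size=t)
    mu *= target_total / mu.sum()
    phi = rng.gamma(phi_shape, phi_scale, size=t)
    return GeneParamTable.from_arrays(mu, phi)


def load_or_sample_params(
    path=None,
    t: int | None = None,
    rng: np.random.Generator | None = None,
    target_total: float = 1.0e7,
) -> GeneParamTable:
    """Read a (gene, mu, phi) TSV, or draw a table from the meta-sampler."""
    if path is not None:
        return GeneParamTable.from_tsv(path)
    if t is None or rng is None:
        raise ValueError("either a path or (t, rng) must be given")
    return sample_params(t, rng, target_total=target_total)
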