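"""Expectation models for embedded-rNMP proportions.

Which ribonucleotide ends up embedded in mtDNA depends on (a) how often
each base is templated — the genome's base composition f_b — (b) the
relative availability of the ribo- versus deoxy-triphosphate in the
mitochondrial pool (r_b/d_b), and (c) how strongly the mitochondrial
replicative polymerase (POLG) discriminates against the ribonucleotide
(discrimination factor DF_b; higher DF, fewer ribos). Four nested
expectation modes:

======================  =============================
composition             w_b = f_b
ratio                   w_b = f_b * (r_b/d_b)
df                      w_b = f_b / DF_b
composite               w_b = f_b * (r_b/d_b) / DF_b
======================  =============================

Expected proportions are w_b / sum(w). Observed call proportions are
compared to each mode by total-variation distance, with a chi-square test
at the observed sample size and a multinomial bootstrap over mode ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import RIBO_BASES, ProportionVector

MODEL_MODES = ("composition", "ratio", "df", "composite")


@dataclass(frozen=True)
class PoolTable:
    """Per-base rNTP and dNTP concentrations (any common unit) and POLG
    discrimination factors, in base order A, C, G, U/T."""

    rntp: tuple[float, float, float, float]
    dntp: tuple[float, float, float, float]
    df: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for name in ("rntp", "dntp", "df"):
            vals = getattr(self, name)
            if len(vals) != 4 or any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be four positive values")

    @property
    def ratio(self) -> np.ndarray:
        """rNTP:dNTP ratio per base."""
        return np.asarray(self.rntp) / np.asarray(self.dntp)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PoolTable":
        """Read a table with columns base, rntp, dntp, df (base order in
        the file is free; A/C/G/U or T accepted)."""
        df = pd.read_csv(path, sep="\t", comment="#")
        df["base"] = df["base"].str.upper().str.replace("T", "U")
        df = df.set_index("base").loc[list(RIBO_BASES)]
        return cls(
            rntp=tuple(df["rntp"].astype(float)),
            dntp=tuple(df["dntp"].astype(float)),
            df=tuple(df["df"].astype(float)),
        )


def expected_proportions(
    mode: str,
    base_comp: ProportionVector,
    pools: PoolTable | None = None,
) -> ProportionVector:
    """Expected embedded-rNMP proportions under one expectation mode."""
    if mode not in MODEL_MODES:
        raise ValueError(f"mode must be one of {MODEL_MODES}, got {mode!r}")
    f = base_comp.as_array()
    w = f.copy()
    if mode != "composition":
        if pools is None:
            raise ValueError(f"mode {mode!r} requires a pool table")
        if mode in ("ratio", "composite"):
            w = w * pools.ratio
        if mode in ("df", "composite"):
            w = w / np.asarray(pools.df)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate weights: all zero")
    return ProportionVector(*(w / total))


def total_variation(p: ProportionVector, q: ProportionVector) -> float:
    return float(0.5 * np.abs(p.as_array() - q.as_array()).sum())


@dataclass
class DivergenceReport:
    tv: float
    chi2: float | None
    chi2_pvalue: float | None
    tv_ci: tuple[float, float]
    n: int
    mode_ranking: list[str] | None = None
    top_mode_fraction: dict[str, float] | None = None


def compare_proportions(
    observed_counts,
    expected: ProportionVector,
    alternatives: dict[str, ProportionVector] | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> DivergenceReport:
    """Divergence of observed call counts from an expectation.

    Reports total-variation distance with a multinomial-bootstrap CI, and
    a chi-square statistic against the expected proportions at the
    observed sample size (undefined when the expectation contains exact
    zeros opposite nonzero counts). When ``alternatives`` maps mode names
    to candidate expectations, the candidates are ranked by distance to
    the observed proportions, with the fraction of bootstrap replicates in
    which each candidate ranks closest.
    """
    counts = np.asarray(observed_counts, dtype=float)
    n = int(counts.sum())
    if n <= 0:
        raise ValueError("observed counts must be positive")
    obs = ProportionVector.from_counts(counts)
    tv = total_variation(obs, expected)

    e = expected.as_array()
    if np.any((e == 0) & (counts > 0)):
        chi2 = chi2_p = None
    else:
        keep = e > 0
        chi2_stat, chi2_p = sps.chisquare(counts[keep], f_exp=n * e[keep] / e[keep].sum())
        chi2, chi2_p = float(chi2_stat), float(chi2_p)

    rng = np.random.default_rng(seed)
    boot = rng.multinomial(n, obs.as_array(), size=n_boot) / n
    tv_boot = 0.5 * np.abs(boot - e).sum(axis=1)
    tv_ci = (float(np.quantile(tv_boot, 0.025)), float(np.quantile(tv_boot, 0.975)))

    ranking = None
    top_fraction = None
    if alternatives:
        names = list(alternatives)
        exp_mat = np.stack([alternatives[m].as_array() for m in names])
        point_tv = 0.5 * np.abs(exp_mat - obs.as_array()).sum(axis=1)
        ranking = [names[i] for i in np.argsort(point_tv, kind="stable")]
        boot_tv = 0.5 * np.abs(boot[:, None, :] - exp_mat[None, :, :]).sum(axis=2)
        winners = np.argmin(boot_tv, axis=1)
        top_fraction = {m: float(np.mean(winners == i)) for i, m in enumerate(names)}
    return DivergenceReport(tv, chi2, chi2_p, tv_ci, n, ranking, top_fraction)


def write_model_report(
    path: str | Path,
    observed: ProportionVector,
    expectations: dict[str, ProportionVector],
    report: DivergenceReport,
) -> None:
    rows = [{"mode": "observed", **{f"p{b}": v for b, v in observed.as_dict().items()}, "tv_to_observed": 0.0}]
    for mode, pv in expectations.items():
        rows.append(
            {
                "mode": mode,
                **{f"p{b}": v for b, v in pv.as_dict().items()},
                "tv_to_observed": total_variation(pv, observed),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
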