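"""Hudson–Kreitman–Aguadé (HKA) test of polymorphism/divergence heterogeneity.

Under neutrality, within-species polymorphism and between-lineage
divergence at a region are both proportional to the region's mutation
rate, so the polymorphism-to-divergence ratio should be homogeneous across
linked regions.  The two-region HKA test fits per-region scaled mutation
rates θ_i and a shared scaled divergence time T by the method of moments

    E[S_i] = θ_i · a_n,        a_n = Σ_{j=1..n−1} 1/j
    E[D_i] = θ_i · (T + 1)

(equal population sizes, single outgroup lineage), and measures departure
with the goodness-of-fit statistic

    X² = Σ_i [(S_i − Ê S_i)² / Var̂ S_i + (D_i − Ê D_i)² / Var̂ D_i]

where Var[S_i] = θ_i a_n + θ_i² b_n (b_n = Σ 1/j²) and
Var[D_i] = θ_i(T+1) + θ_i².  Significance comes from χ²(df=1) or,
optionally, from neutral coalescent simulation at the fitted parameters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import Alignment, hamming


def harmonic(n: int, power: int = 1) -> float:
    """a_n (power=1) or b_n (power=2): Σ_{j=1..n−1} 1/j^power."""
    return float(sum(1.0 / j ** power for j in range(1, n)))


@dataclass
class RegionCounts:
    """Polymorphism and divergence summary of one genomic region."""

    name: str
    S: float        # segregating sites within the ingroup
    D: float        # mean pairwise differences ingroup <-> outgroup
    n: int          # ingroup sample size
    L_sites: int | None = None

    def __post_init__(self) -> None:
        if self.S < 0 or self.D < 0:
            raise ValueError("S and D must be >= 0")
        if self.n < 2:
            raise ValueError("ingroup sample size must be >= 2")


@dataclass
class HKAResult:
    theta_hat: tuple[float, float]
    T_hat: float
    X2: float
    df: int
    p_chi2: float
    p_sim: float | None = None
    expected: dict = field(default_factory=dict)
    regions: tuple[str, str] = ("region1", "region2")


def region_counts(ingroup: Alignment, outgroup: str, name: str = "region"
                  ) -> RegionCounts:
    """Summarize an aligned region as (S, D, n).

    S counts ingroup columns with more than one base after listwise
    exclusion of columns carrying a gap or ambiguity in any sequence
    (ingroup or outgroup); D is the mean, over ingroup sequences, of
    nucleotide differences to the single outgroup sequence on the retained
    columns.
    """
    if ingroup.n < 2:
        raise ValueError("ingroup must contain at least 2 sequences")
    if len(outgroup) != ingroup.length:
        raise ValueError("outgroup not aligned with ingroup")
    mat = ingroup.matrix()
    out = np.array(list(outgroup.upper()), dtype="U1")
    valid_in = np.all(np.isin(mat, list("ACGT")), axis=0)
    valid = valid_in & np.isin(out, list("ACGT"))
    mat = mat[:, valid]
    out = out[valid]
    S = int(np.sum(np.any(mat != mat[0], axis=0)))
    D = float(np.mean(np.sum(mat != out[None, :], axis=1)))
    return RegionCounts(name=name, S=S, D=D, n=ingroup.n,
                        L_sites=int(valid.sum()))


def _fit_moments(S1: float, D1: float, S2: float, D2: float, a: float
                 ) -> tuple[float, float, float]:
    """Fit (θ1, θ2, T) by bounded least squares on the moment equations.

    The three classical moment conditions are Σ S_i = a·(θ1+θ2),
    Σ D_i = (T+1)·(θ1+θ2) and S_2 + D_2 = θ2·(a + T + 1).  A closed-form
    interior solution exists whenever counts are positive and is used as
    the starting point; bounds θ_i ≥ 1e−9, T ≥ 0 let the same machinery
    absorb degenerate counts (e.g. S = 0 regions) without special-casing.
    """
    sumS, sumD = S1 + S2, D1 + D2
    # closed-form start where well-defined
    if sumS > 0 and sumD >= 0:
        t = a * sumD / sumS  # = T + 1
        theta_tot = sumS / a
        theta2 = (S2 + D2) / (a + t) if (a + t) > 0 else theta_tot / 2
        theta1 = theta_tot - theta2
        x0 = [max(theta1, 1e-6), max(theta2, 1e-6), max(t - 1.0, 0.0)]
    else:
        x0 = [1e-3, 1e-3, 1.0]

    def residuals(x):
        th1, th2, T = x
        return [
            sumS - a * (th1 + th2),
            sumD - (T + 1.0) * (th1 + th2),
            (S2 + D2) - th2 * (a + T + 1.0),
        ]

    sol = optimize.least_squares(
        residuals, x0, bounds=([1e-9, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"HKA moment solve did not converge: {sol.message}")
    th1, th2, T = sol.x
    return float(th1), float(th2), float(T)


def _x2(S: list[float], D: list[float], thetas: list[float], T: float,
        a: float, b: float) -> tuple[float, dict]:
    X2 = 0.0
    expected: dict = {}
    for i, (s, d, th) in enumerate(zip(S, D, thetas)):
        eS = th * a
        eD = th * (T + 1.0)
        vS = th * a + th ** 2 * b
        vD = th * (T + 1.0) + th ** 2
        for obs, exp, var in ((s, eS, vS), (d, eD, vD)):
            res = obs - exp
            if var > 1e-12:
                X2 += res ** 2 / var
            elif abs(res) > 1e-6:
                X2 += np.inf
        expected[f"region{i + 1}"] = {
            "E_S": eS, "E_D": eD, "Var_S": vS, "Var_D": vD}
    return float(X2), expected


def hka_test(region1: RegionCounts, region2: RegionCounts,
             sim_reps: int = 0, seed: int | None = None,
             region_lengths: tuple[int, int] | None = None) -> HKAResult:
    """Two-region HKA test of polymorphism/divergence heterogeneity.

    Both regions must share the ingroup sample size n.  The p-value is
    taken from χ²(df=1) by default; with ``sim_reps`` > 0 a simulation
    p-value is added — the fraction of neutral coalescent replicates at the
    fitted (θ̂1, θ̂2, T̂) whose X² meets or exceeds the observed value.

    Degenerate all-zero counts give X² = 0, p = 1 with a warning.
    """
    if region1.n != region2.n:
        raise ValueError("regions must share the ingroup sample size")
    n = region1.n
    a, b = harmonic(n, 1), harmonic(n, 2)
    S = [region1.S, region2.S]
    D = [region1.D, region2.D]

    if sum(S) + sum(D) == 0:
        warnings.warn("all counts zero: X2=0, p=1")
        return HKAResult((0.0, 0.0), 0.0, 0.0, 1, 1.0,
                         regions=(region1.name, region2.name))

    th1, th2, T = _fit_moments(S[0], D[0], S[1], D[1], a)
    X2, expected = _x2(S, D, [th1, th2], T, a, b)
    p_chi2 = float(stats.chi2.sf(X2, df=1))

    p_sim = None
    if sim_reps > 0:
        from .simulate import SimSequenceParams, simulate_two_region_data

        rng = np.random.default_rng(seed)
        lengths = region_lengths or (
            region1.L_sites or 10000, region2.L_sites or 10000)
        exceed = 0
        for _ in range(sim_reps):
            # per-region theta: simulate each region at its fitted theta
            rep_counts = []
            for th, L in zip((th1, th2), lengths):
                p = SimSequenceParams(
                    theta_per_region=th, divergence_time=T, n_ingroup=n,
                    region_lengths=(L,), divergence_inflation=(1.0,),
                    seed=int(rng.integers(2 ** 31)))
                aligns, outs = simulate_two_region_data(p)
                rep_counts.append(region_counts(aligns[0], outs[0]))
            r1, r2 = rep_counts
            if r1.S + r1.D + r2.S + r2.D == 0:
                rep_X2 = 0.0
            else:
                t1, t2, Tr = _fit_moments(r1.S, r1.D, r2.S, r2.D, a)
                rep_X2, _ = _x2([r1.S, r2.S], [r1.D, r2.D], [t1, t2], Tr, a, b)
            if rep_X2 >= X2:
                exceed += 1
        p_sim = exceed / sim_reps

    return HKAResult((th1, th2), T, X2, 1, p_chi2, p_sim, expected,
                     regions=(region1.name, region2.name))


def hka_panel(regions: list[RegionCounts], alpha_levels: tuple[float, float]
              = (0.05, 0.01), **kwargs) -> pd.DataFrame:
    """All pairwise HKA tests among a set of regions.

    Returns one row per unordered region pair with X², p-values and
    significance stars at the two alpha levels (default 0.05 → ``*`` and
    0.01 → ``**``).
    """
    rows = []
    for r1, r2 in itertools.combinations(regions, 2):
        res = hka_test(r1, r2, **kwargs)
        stars = ""
        if res.p_chi2 < alpha_levels[1]:
            stars = "**"
        elif res.p_chi2 < alpha_levels[0]:
            stars = "*"
        rows.append({
            "region1": r1.name, "region2": r2.name,
            "S1": r1.S, "D1": r1.D, "S2": r2.S, "D2": r2.D,
            "theta1": res.theta_hat[0], "theta2": res.theta_hat[1],
            "T": res.T_hat, "X2": res.X2, "p_chi2": res.p_chi2,
            "p_sim": res.p_sim, "significance": stars,
        })
    return pd.DataFrame(rows)
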