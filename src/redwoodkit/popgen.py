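"""Windowed nucleotide diversity and Weir-Cockerham Fst.

Per-site diversity follows the unbiased pairwise estimator
pi = 2 j (n - j) / (n (n - 1)) for j alternate alleles among n non-missing
alleles; window values divide the summed site pi by the window length
(per-bp diversity), with windows anchored at position 1 and advancing by
the step (VCFtools convention, 1-based inclusive window bounds).

Fst uses the Weir & Cockerham (1984) variance decomposition for diploids
with observed heterozygosity and unequal sample sizes: per-site components
a (among populations), b (among individuals within populations), and
c (within individuals), combined per window as the ratio of sums
theta = sum(a) / sum(a + b + c). Negative estimates are reported as
computed; missing genotypes reduce per-population sample sizes rather
than dropping the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import VariantTable

DEFAULT_WINDOW = 10_000
DEFAULT_STEP = 1_000


@dataclass
class PiWindow:
    scaffold: str
    start: int  # 1-based inclusive
    end: int
    pi: float
    n_sites: int


@dataclass
class FstComponents:
    """Per-site W&C variance components for the informative sites."""

    scaffolds: list[str]
    positions: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def per_site_theta(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)

    def ratio_of_sums(self) -> float:
        denom = float(np.sum(self.a + self.b + self.c))
        if denom == 0:
            raise ValueError("no informative variation for Fst")
        return float(np.sum(self.a)) / denom

    def mean_of_ratios(self) -> float:
        theta = self.per_site_theta
        return float(np.nanmean(theta))


@dataclass
class FstWindow:
    scaffold: str
    start: int
    end: int
    theta: float
    n_sites: int


def site_pi(genotypes: np.ndarray) -> float:
    """Per-site diversity from one row of diploid dosages (missing = -1)."""
    g = np.asarray(genotypes)
    ok = g >= 0
    n = 2 * int(np.sum(ok))
    if n < 2:
        raise ValueError("site needs at least two non-missing alleles")
    j = int(np.sum(g[ok]))
    return 2 * j * (n - j) / (n * (n - 1))


def _window_starts(last_pos: int, window: int, step: int) -> range:
    return range(1, max(last_pos, 1) + 1, step)


def windowed_pi(
    table: VariantTable, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
) -> list[PiWindow]:
    """Sliding-window per-bp diversity, windows anchored at position 1.

    Windows within the covered scaffold span (up to the last variant) are
    reported, including empty ones at pi = 0.
    """
    out: list[PiWindow] = []
    for scaffold in dict.fromkeys(table.scaffolds):
        idx = [i for i, sc in enumerate(table.scaffolds) if sc == scaffold]
        pos = table.positions[idx]
        pis = np.zeros(len(idx))
        for k, i in enumerate(idx):
            g = table.genotypes[i]
            if np.sum(g >= 0) * 2 >= 2:
                pis[k] = site_pi(g)
        last = int(pos.max()) if len(pos) else 0
        for start in _window_starts(last, window, step):
            end = start + window - 1
            in_win = (pos >= start) & (pos <= end)
            out.append(
                PiWindow(
                    scaffold=scaffold,
                    start=start,
                    end=end,
                    pi=float(np.sum(pis[in_win])) / window,
                    n_sites=int(np.sum(in_win)),
                )
            )
    return out


def pi_summary(windows: list[PiWindow], table: VariantTable) -> dict[str, float]:
    """Both averaging conventions: over windows and over variant sites."""
    per_site = []
    for i in range(table.n_sites):
        g = table.genotypes[i]
        if np.sum(g >= 0) * 2 >= 2:
            per_site.append(site_pi(g))
    return {
        "mean_pi_over_windows": float(np.mean([w.pi for w in windows])) if windows else 0.0,
        "mean_pi_over_sites": float(np.mean(per_site)) if per_site else 0.0,
    }


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst


def wc_components(table: VariantTable) -> FstComponents:
    """Per-site W&C (1984) a, b, c for every informative biallelic site.

    A site is informative when at least two populations each contribute at
    least one non-missing diploid genotype (and the average sample size
    exceeds one individual, so the estimator's denominators exist).
    """
    pops = table.population_indices()
    if len(pops) < 2:
        raise ValueError("Fst needs at least two populations")
    pop_cols = list(pops.values())

    scaffolds: list[str] = []
    positions: list[int] = []
    avals: list[float] = []
    bvals: list[float] = []
    cvals: list[float] = []
    for i in range(table.n_sites):
        g = table.genotypes[i]
        n_i, p_i, h_i = [], [], []
        for cols in pop_cols:
            gp = g[cols]
            ok = gp >= 0
            ni = int(np.sum(ok))
            if ni == 0:
                continue
            n_i.append(ni)
            p_i.append(float(np.sum(gp[ok])) / (2 * ni))
            h_i.append(float(np.sum(gp[ok] == 1)) / ni)
        r = len(n_i)
        if r < 2:
            continue
        n_arr = np.array(n_i, dtype=float)
        p_arr = np.array(p_i)
        h_arr = np.array(h_i)
        nbar = n_arr.mean()
        if nbar <= 1:
            continue
        nsum = n_arr.sum()
        nc = (nsum - np.sum(n_arr**2) / nsum) / (r - 1)
        if nc == 0:
            continue
        pbar = np.sum(n_arr * p_arr) / nsum
        s2 = np.sum(n_arr * (p_arr - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n_arr * h_arr) / nsum
        a = (nbar / nc) * (
            s2
            - (1 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        scaffolds.append(table.scaffolds[i])
        positions.append(int(table.positions[i]))
        avals.append(float(a))
        bvals.append(float(b))
        cvals.append(float(c))
    return FstComponents(
        scaffolds=scaffolds,
        positions=np.array(positions, dtype=np.int64),
        a=np.array(avals),
        b=np.array(bvals),
        c=np.array(cvals),
    )


def wc_fst(
    table: VariantTable,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    mean_of_ratios: bool = False,
) -> tuple[FstComponents, list[FstWindow]]:
    """Per-site components plus windowed theta (ratio of sums by default).

    Only windows containing at least one informative site are emitted.
    """
    comp = wc_components(table)
    windows: list[FstWindow] = []
    for scaffold in dict.fromkeys(comp.scaffolds):
        idx = np.array([i for i, sc in enumerate(comp.scaffolds) if sc == scaffold])
        pos = comp.positions[idx]
        last = int(pos.max()) if len(pos) else 0
        for start in _window_starts(last, window, step):
            end = start + window - 1
            sel = idx[(pos >= start) & (pos <= end)]
            if len(sel) == 0:
                continue
            if mean_of_ratios:
                denom = comp.a[sel] + comp.b[sel] + comp.c[sel]
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratios = np.where(denom != 0, comp.a[sel] / denom, np.nan)
                theta = float(np.nanmean(ratios))
            else:
                denom_sum = float(np.sum(comp.a[sel] + comp.b[sel] + comp.c[sel]))
                theta = float(np.sum(comp.a[sel])) / denom_sum if denom_sum else float("nan")
            windows.append(FstWindow(scaffold, start, end, theta, len(sel)))
    return comp, windows


def fst_summary(comp: FstComponents, windows: list[FstWindow]) -> dict[str, float]:
    return {
        "global_ratio_of_sums": comp.ratio_of_sums(),
        "mean_theta_over_windows": float(np.nanmean([w.theta for w in windows]))
        if windows
        else float("nan"),
    }
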