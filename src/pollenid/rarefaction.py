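"""Species-accumulation (rarefaction) curves over sequenced clones.

Individual-based rarefaction: the x-axis is the number of clones sequenced,
pooled over the three collection dates of a site, separately per marker. Two
estimators are provided:

* ``accumulation_permutation`` — the mean running distinct-taxon count over
  random orderings of the pooled clones (1,000 iterations by default);
* ``accumulation_analytic`` — the exact hypergeometric expectation
  ``E[S_n] = Σ_i (1 − C(N−N_i, n) / C(N, n))``, the closed form the
  permutation estimate converges to.

Unidentifiable MOTUs are counted as distinct pseudo-taxa by default: their
clones are real sequences of real (unnamed) taxa, and dropping them would
bias the curve downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .assignment import CALL_GENUS, CALL_SPECIES, AssignmentResult
from .errors import ValidationError
from .motu import MOTU


@dataclass
class AccumulationCurve:
    """Expected distinct taxa as a function of sequencing depth (1..N)."""

    depths: np.ndarray
    mean_richness: np.ndarray
    sd_richness: np.ndarray | None
    n_iterations: int
    method: str  # "permutation" | "analytic"

    def to_frame(self) -> pd.DataFrame:
        sd = (
            self.sd_richness
            if self.sd_richness is not None
            else np.full(len(self.depths), np.nan)
        )
        return pd.DataFrame(
            {"depth": self.depths, "mean_richness": self.mean_richness, "sd_richness": sd}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def pool_site_labels(
    results: list[tuple[MOTU, AssignmentResult]],
    site: str,
    marker: str,
    count_unidentifiable: bool = True,
) -> list[str]:
    """One taxon label per clone for a site × marker, pooled over dates.

    Identified MOTUs (species- or genus-level) contribute their call name once
    per member clone. Unidentifiable or ambiguous MOTUs contribute a pseudo-
    label unique to the MOTU (they are detected sequences of unseen taxa);
    set ``count_unidentifiable=False`` to drop them instead.
    """
    labels: list[str] = []
    seen_site = False
    for motu, result in results:
        if motu.marker != marker:
            continue
        if motu.site != site:
            continue
        seen_site = True
        if result.call_level in (CALL_SPECIES, CALL_GENUS):
            label = result.call_name
        elif count_unidentifiable:
            label = f"unassigned:{motu.site}|{motu.date}|{motu.marker}|{motu.motu_id}"
        else:
            continue
        labels.extend([label] * motu.n_clones)
    if not seen_site:
        raise ValidationError(f"no assignments for site {site!r}, marker {marker!r}")
    return labels


def accumulation_permutation(
    labels: list[str], n_iter: int = 1000, seed: int | None = None
) -> AccumulationCurve:
    """Randomised accumulation curve: mean ± sd of the running distinct-label
    count over ``n_iter`` uniform random orderings. Deterministic under seed."""
    if not labels:
        raise ValidationError("cannot rarefy an empty label list")
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    codes = pd.factorize(np.asarray(labels))[0]
    n = len(codes)
    rng = np.random.default_rng(seed)
    acc = np.zeros(n)
    acc2 = np.zeros(n)
    for _ in range(n_iter):
        perm = rng.permutation(n)
        shuffled = codes[perm]
        # first occurrence position of each label in this ordering
        first = np.full(codes.max() + 1, n, dtype=np.int64)
        np.minimum.at(first, shuffled, np.arange(n))
        richness = np.cumsum(np.bincount(first, minlength=n + 1)[:n])
        acc += richness
        acc2 += richness.astype(float) ** 2
    mean = acc / n_iter
    var = np.maximum(acc2 / n_iter - mean**2, 0.0)
    return AccumulationCurve(
        depths=np.arange(1, n + 1),
        mean_richness=mean,
        sd_richness=np.sqrt(var),
        n_iterations=n_iter,
        method="permutation",
    )


def accumulation_analytic(abundance_vector: list[int]) -> AccumulationCurve:
    """Exact expected accumulation curve from per-taxon clone counts.

    ``E[S_n] = Σ_i [1 − C(N−N_i, n) / C(N, n)]`` with ``N = Σ N_i``; binomial
    coefficients are evaluated in log space so depths of several hundred
    clones cannot overflow.
    """
    counts = np.asarray(abundance_vector, dtype=np.int64)
    if counts.size == 0 or (counts < 1).any():
        raise ValidationError("abundances must all be >= 1")
    total = int(counts.sum())

    def log_choose(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    depths = np.arange(1, total + 1)
    mean = np.empty(total)
    for j, n in enumerate(depths):
        rest = total - counts
        term = np.zeros(len(counts))
        ok = rest >= n  # else the taxon is certainly seen: P(absent) = 0
        term[ok] = np.exp(log_choose(rest[ok], n) - log_choose(total, n))
        mean[j] = float(np.sum(1.0 - term))
    return AccumulationCurve(
        depths=depths,
        mean_richness=mean,
        sd_richness=None,
        n_iterations=0,
        method="analytic",
    )


def labels_to_abundances(labels: list[str]) -> list[int]:
    """Per-taxon clone counts from a pooled label list."""
    return pd.Series(labels).value_counts().tolist()


def plot_curve(curve: AccumulationCurve, path: str | Path, title: str = "") -> None:
    """Optional curve plot (mean ± sd band) written to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.depths, curve.mean_richness, lw=1.5)
    if curve.sd_richness is not None:
        ax.fill_between(
            curve.depths,
            curve.mean_richness - curve.sd_richness,
            curve.mean_richness + curve.sd_richness,
            alpha=0.3,
        )
    ax.set_xlabel("clones sequenced")
    ax.set_ylabel("distinct taxa")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
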