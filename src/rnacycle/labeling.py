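"""Bayesian classification of labeled (newly synthesized) molecules.

Metabolic labeling with 4sU marks nascent RNA with T→C conversions, but a
sequenced conversion can also be a sequencing error, and an unconverted
molecule can still be newly synthesized (incomplete 4sU incorporation).
Classification therefore runs in two Bayesian stages:

1. per locus, the posterior that an observed mismatch pattern (k supporting
   reads out of n covering) reflects a true conversion rather than
   sequencing error — a two-component binomial mixture with success rates
   ``1 - εs`` (true conversion) and ``εs`` (error), mixed by the
   sample-level conversion prior ρ;
2. per molecule, the posterior that the molecule is newly synthesized given
   its expected conversion count ``km`` (the sum of locus posteriors) and
   its number of observed reference Ts ``nm`` — a Poisson(nm·ρl) component
   for labeled molecules against a Binomial(nm, εc) false-positive
   component, mixed by the per-gene prior θ.

Summing the molecule posteriors per gene and cell, split by splice status,
yields the four count matrices (labeled/unlabeled × precursor/mature) that
feed the kinetic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import gammaln
from scipy.stats import binom, poisson

from .reads import AMBIGUOUS, SPLICED, MoleculeRecord

logger = logging.getLogger(__name__)

PRIOR_FLOOR = 1e-6


@dataclass
class ConversionPriors:
    """Parameters of the two classification stages.

    eps_s — per-base sequencing error rate (default 0.1%);
    eps_c — conversion false-positive rate in unlabeled molecules
            (default 1.8e-4, from unlabeled control libraries);
    rho   — sample-level conversion prior;
    rho_l — conversion rate in labeled molecules (4sU incorporation ×
            conversion efficiency), estimated from a saturation experiment;
    theta — per-gene prior fraction of newly synthesized molecules.
    """

    eps_s: float = 0.001
    eps_c: float = 1.8e-4
    rho: float = 0.02
    rho_l: float = 0.024
    theta: dict[str, float] | float = 0.5

    def __post_init__(self):
        for name in ("eps_s", "eps_c", "rho", "rho_l"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def theta_for(self, gene: str) -> float:
        if isinstance(self.theta, dict):
            return self.theta[gene]
        return float(self.theta)


def conversion_posterior(k, n, eps_s: float, rho: float):
    """Posterior probability that a locus carries a true T→C conversion.

    ``pc = ρ·B(k; n, 1-εs) / (ρ·B(k; n, 1-εs) + (1-ρ)·B(k; n, εs))`` for k
    supporting reads out of n covering.  Vectorized over k, n.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k < 0) or np.any(n < 0):
        raise ValueError("k and n must be non-negative")
    if np.any(k > n):
        raise ValueError("k cannot exceed n")
    if not 0.0 <= eps_s <= 1.0 or not 0.0 <= rho <= 1.0:
        raise ValueError("eps_s and rho must be in [0, 1]")
    lik_true = binom.pmf(k, n, 1.0 - eps_s)
    lik_err = binom.pmf(k, n, eps_s)
    num = rho * lik_true
    den = num + (1.0 - rho) * lik_err
    with np.errstate(invalid="ignore", divide="ignore"):
        pc = np.where(den > 0, num / np.maximum(den, 1e-300), rho)
    return pc if pc.ndim else float(pc)


def molecule_conversion_count(
    molecule: MoleculeRecord, eps_s: float, rho: float
) -> float:
    """Expected number of true conversions: Σ over loci of the posterior."""
    if not molecule.loci:
        return 0.0
    ks = np.array([k for _pos, _n, k in molecule.loci])
    ns = np.array([n for _pos, n, _k in molecule.loci])
    return float(np.sum(conversion_posterior(ks, ns, eps_s, rho)))


def _poisson_pmf_continuous(k, lam):
    """Poisson pmf with the factorial continued through Γ (for real k)."""
    lam = np.maximum(np.asarray(lam, dtype=float), 1e-300)
    return np.exp(k * np.log(lam) - lam - gammaln(k + 1.0))


def new_molecule_posterior(
    km, nm, rho_l: float, eps_c: float, theta: float, continuous: bool = False
):
    """Posterior probability that a molecule is newly synthesized.

    ``pnew = θ·Pois(km; nm·ρl) / (θ·Pois(km; nm·ρl) + (1-θ)·B(km; nm, εc))``.
    ``km`` (a sum of locus posteriors) is real-valued; by default it is
    rounded to the nearest integer for the pmf evaluation, with
    ``continuous=True`` the factorials are continued through Γ.
    """
    km = np.asarray(km, dtype=float)
    nm = np.asarray(nm)
    if np.any(km < 0) or np.any(nm < 0):
        raise ValueError("km and nm must be non-negative")
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    lam = nm * rho_l
    if continuous:
        lik_new = _poisson_pmf_continuous(km, lam)
        k_int = km
    else:
        k_int = np.round(km)
        lik_new = poisson.pmf(k_int, lam)
    k_binom = np.minimum(k_int, nm)  # binomial support is 0..nm
    lik_old = binom.pmf(k_binom, nm, eps_c)
    lik_old = np.where(k_int > nm, 0.0, lik_old)
    num = theta * lik_new
    den = num + (1.0 - theta) * lik_old
    with np.errstate(invalid="ignore", divide="ignore"):
        pnew = np.where(den > 0, num / np.maximum(den, 1e-300), theta)
    return pnew if pnew.ndim else float(pnew)


def _is_confident(n: int, k: int) -> bool:
    """More than half of the covering reads support the conversion."""
    return n > 0 and k / n > 0.5


def estimate_conversion_prior(molecules, floor: float = PRIOR_FLOOR) -> float:
    """Sample-level conversion prior ρ.

    Ratio of confident conversion loci (more than 50% of covering reads
    converted) to the total number of reference-T positions observed across
    all molecules, clamped to (floor, 1 - floor).
    """
    molecules = list(molecules)
    if not molecules:
        raise ValueError("no molecules")
    total_t = sum(m.n_T for m in molecules)
    if total_t == 0:
        raise ValueError("no observed T positions")
    confident = sum(
        1 for m in molecules for _pos, n, k in m.loci if _is_confident(n, k)
    )
    return float(np.clip(confident / total_t, floor, 1.0 - floor))


def estimate_theta(
    molecules, floor: float = PRIOR_FLOOR
) -> dict[str, float]:
    """Per-gene prior fraction of newly synthesized molecules.

    Fraction of a gene's molecules carrying at least one confident
    conversion locus.  Genes without molecules are skipped with a log entry
    (they cannot appear here by construction, but callers may pass
    pre-grouped inputs).
    """
    counts: dict[str, list[int]] = {}
    for m in molecules:
        has_conv = any(_is_confident(n, k) for _pos, n, k in m.loci)
        tot_conv = counts.setdefault(m.gene, [0, 0])
        tot_conv[0] += 1
        tot_conv[1] += int(has_conv)
    theta = {}
    for gene, (total, converted) in counts.items():
        if total == 0:
            logger.warning("gene %s has no molecules; skipped", gene)
            continue
        theta[gene] = float(np.clip(converted / total, floor, 1.0))
    return theta


def estimate_rho_l(molecules, pooled: bool = True) -> float:
    """Conversion rate in labeled molecules from a saturation experiment.

    After labeling for a full turnover time (e.g. 24 h), essentially every
    precursor molecule is newly synthesized, so the pooled conversion ratio
    Σ conversions / Σ Ts over precursor molecules estimates ρl.  With
    ``pooled=False`` the mean of per-molecule ratios is returned instead.
    """
    molecules = [m for m in molecules if m.n_T > 0]
    if not molecules:
        raise ValueError("no molecules with observed Ts")
    conv = np.array(
        [sum(1 for _pos, n, k in m.loci if _is_confident(n, k)) for m in molecules]
    )
    ts = np.array([m.n_T for m in molecules])
    if pooled:
        return float(conv.sum() / ts.sum())
    return float(np.mean(conv / ts))


def classify_molecules(
    molecules, priors: ConversionPriors, continuous: bool = False
) -> pd.DataFrame:
    """Per-molecule labeling posterior table.

    Returns a DataFrame with cell_barcode, umi, gene, n_T, km, pnew and
    splice_status.  θ may be a per-gene mapping (genes missing from it fall
    back to nothing — estimate θ first) or a scalar.
    """
    rows = []
    for m in molecules:
        km = molecule_conversion_count(m, priors.eps_s, priors.rho)
        pnew = new_molecule_posterior(
            km, m.n_T, priors.rho_l, priors.eps_c, priors.theta_for(m.gene),
            continuous=continuous,
        )
        rows.append(
            {
                "cell_barcode": m.cell_barcode,
                "umi": m.umi,
                "gene": m.gene,
                "n_T": m.n_T,
                "km": km,
                "pnew": pnew,
                "splice_status": m.splice_status,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LabeledCounts:
    """Four gene × cell matrices of posterior-weighted molecule counts.

    Entries are sums of labeling posteriors (labeled matrices) or their
    complements (unlabeled matrices), so ``pl + pu`` and ``ml + mu``
    reproduce the raw precursor and mature molecule counts exactly.
    """

    genes: list
    barcodes: list
    pl: sparse.spmatrix
    ml: sparse.spmatrix
    pu: sparse.spmatrix
    mu: sparse.spmatrix
    cells: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        shape = (len(self.genes), len(self.barcodes))
        for name in ("pl", "ml", "pu", "mu"):
            mat = getattr(self, name)
            if mat.shape != shape:
                raise ValueError(f"{name} has shape {mat.shape}, expected {shape}")
            if mat.size and mat.min() < 0:
                raise ValueError(f"{name} has negative entries")

    @property
    def species(self):
        return {"pl": self.pl, "ml": self.ml, "pu": self.pu, "mu": self.mu}

    def cell_totals(self) -> np.ndarray:
        """Total molecules captured per cell, over all four species."""
        return np.asarray(
            sum(m.sum(axis=0) for m in self.species.values())
        ).ravel()


def assemble_count_matrices(
    classified: pd.DataFrame, cells: pd.DataFrame
) -> LabeledCounts:
    """Posterior-weighted count matrices from classified molecules.

    Spliced molecules contribute ``pnew`` to ml and ``1 - pnew`` to mu of
    their gene and cell; unspliced molecules likewise to pl/pu.  Ambiguous
    splice calls contribute nothing.  ``cells`` must contain a
    ``cell_barcode`` column covering every barcode in ``classified``.
    """
    known = set(cells["cell_barcode"])
    seen = set(classified["cell_barcode"])
    unknown = seen - known
    if unknown:
        raise ValueError(f"barcodes missing from cell metadata: {sorted(unknown)[:5]}")
    barcodes = list(cells["cell_barcode"])
    genes = sorted(classified["gene"].unique())
    g_idx = {g: i for i, g in enumerate(genes)}
    c_idx = {c: i for i, c in enumerate(barcodes)}
    shape = (len(genes), len(barcodes))
    acc = {name: sparse.lil_matrix(shape) for name in ("pl", "ml", "pu", "mu")}
    usable = classified[classified["splice_status"] != AMBIGUOUS]
    for row in usable.itertuples(index=False):
        gi = g_idx[row.gene]
        ci = c_idx[row.cell_barcode]
        labeled, unlabeled = (
            ("ml", "mu") if row.splice_status == SPLICED else ("pl", "pu")
        )
        acc[labeled][gi, ci] += row.pnew
        acc[unlabeled][gi, ci] += 1.0 - row.pnew
    return LabeledCounts(
        genes=genes,
        barcodes=barcodes,
        pl=acc["pl"].tocsr(),
        ml=acc["ml"].tocsr(),
        pu=acc["pu"].tocsr(),
        mu=acc["mu"].tocsr(),
        cells=cells.reset_index(drop=True),
    )
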