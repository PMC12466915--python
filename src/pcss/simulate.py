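"""Forward simulator for pooled phenotype-sorting experiments.

Generates the full chain the analysis consumes: haploid genotypes at given
allele frequencies, proportional-hazards survival times, sorting of the
cohort into phenotypic bins, and binomial read sampling of each bin's pool
— plus individual-level knockdown assays and qPCR tables with known ground
truth.  Defaults mirror the starvation-cage design: 2000 males per
replicate, two replicates, seven bins, ~200x pooled depth.

Everything is driven by ``numpy.random.Generator`` so a seed fixes the
whole experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_population",
    "bin_individuals",
    "sequence_pools",
    "simulate_experiment",
    "simulate_assay",
    "simulate_qpcr",
]


@dataclass
class SimConfig:
    """Parameters of one simulated cage experiment.

    ``betas`` are per-locus log hazard ratios per ALT allele; the baseline
    hazard is exponential with mean ``1/baseline_rate`` hours (default 80 h,
    in the range of starved flies) or Gompertz ``a * exp(b t)``.
    ``depth_mean`` is the Poisson mean read depth per bin and locus;
    ``seq_error`` a symmetric per-read miscall rate.
    """

    n_individuals: int = 2000
    n_loci: int = 1
    allele_freqs: float | np.ndarray = 0.3
    betas: float | np.ndarray = 0.0
    baseline: str = "exponential"
    baseline_rate: float = 1.0 / 80.0  # per hour
    gompertz_a: float = 1e-3
    gompertz_b: float = 0.05
    n_bins: int = 7
    bin_scheme: str = "equal_count"
    window_h: float = 12.0
    depth_mean: float = 200.0
    seq_error: float = 0.001
    replicates: int = 2
    diploid: bool = False
    seed: int | None = None

    def __post_init__(self):
        self.allele_freqs = np.broadcast_to(
            np.asarray(self.allele_freqs, dtype=float), (self.n_loci,)
        ).copy()
        self.betas = np.broadcast_to(
            np.asarray(self.betas, dtype=float), (self.n_loci,)
        ).copy()
        if np.any((self.allele_freqs < 0) | (self.allele_freqs > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not 0 <= self.seq_error < 1:
            raise ValueError("seq_error must lie in [0, 1)")
        if self.baseline not in ("exponential", "gompertz"):
            raise ValueError(f"unknown baseline: {self.baseline!r}")


@dataclass
class SimTruth:
    """Ground truth of one replicate: genotypes, times, bin membership."""

    genotypes: np.ndarray  # (n_individuals, n_loci), allele dosage
    times: np.ndarray  # (n_individuals,) hours
    betas: np.ndarray  # (n_loci,)
    bin_of: np.ndarray | None = None  # filled by bin_individuals
    ploidy: int = 1


def simulate_population(config: SimConfig, rng: np.random.Generator) -> SimTruth:
    """Draw genotypes and survival times under the proportional-hazards model.

    Haploid (male) genotypes are Bernoulli(freq) per locus; the individual
    hazard is the baseline scaled by ``exp(sum(beta * g))``.
    """
    n, L = config.n_individuals, config.n_loci
    ploidy = 2 if config.diploid else 1
    genotypes = rng.binomial(ploidy, config.allele_freqs, size=(n, L)).astype(np.int8)
    eta = genotypes @ config.betas
    scale = np.exp(eta)
    if config.baseline == "exponential":
        times = rng.exponential(1.0 / (config.baseline_rate * scale))
    else:
        # S(t) = exp(-(a/b) e^eta (e^{bt} - 1)); invert U ~ Uniform(0,1)
        u = rng.uniform(size=n)
        a, b = config.gompertz_a, config.gompertz_b
        times = np.log1p(-b * np.log(u) / (a * scale)) / b
    return SimTruth(genotypes=genotypes, times=times, betas=config.betas, ploidy=ploidy)


def bin_individuals(
    truth: SimTruth,
    n_bins: int = 7,
    scheme: str = "equal_count",
    window_h: float = 12.0,
    replicate: str = "A",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sort individuals by survival time into phenotypic bins.

    ``equal_count`` splits the time-ordered cohort into ``n_bins`` groups
    of size n // n_bins, with the remainder going to the earliest bins
    (mimicking collection of dead flies in waves).  ``fixed_windows`` bins
    by consecutive ``window_h``-hour collection windows; empty windows are
    dropped and bins renumbered.  Returns the bin manifest (replicate,
    bin_index, mean_survival_h, n_individuals) and each individual's bin.
    """
    times = truth.times
    n = len(times)
    if n < n_bins:
        raise ValueError(f"cannot form {n_bins} bins from {n} individuals")
    if scheme == "equal_count":
        order = np.argsort(times, kind="stable")
        base, rem = divmod(n, n_bins)
        sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
        bin_of = np.empty(n, dtype=int)
        start = 0
        for i, sz in enumerate(sizes):
            bin_of[order[start : start + sz]] = i + 1
            start += sz
    elif scheme == "fixed_windows":
        raw = np.floor(times / window_h).astype(int)
        occupied = np.unique(raw)
        remap = {w: i + 1 for i, w in enumerate(occupied)}
        bin_of = np.array([remap[w] for w in raw])
    else:
        raise ValueError(f"unknown bin scheme: {scheme!r}")
    rows = []
    for b in np.unique(bin_of):
        member = bin_of == b
        rows.append(
            {
                "replicate": replicate,
                "bin_index": int(b),
                "mean_survival_h": float(times[member].mean()),
                "n_individuals": int(member.sum()),
            }
        )
    manifest = pd.DataFrame(rows).sort_values("bin_index", ignore_index=True)
    truth.bin_of = bin_of
    return manifest, bin_of


def sequence_pools(
    bin_of: np.ndarray,
    truth: SimTruth,
    depth_mean: float,
    seq_error: float,
    rng: np.random.Generator,
    replicate: str = "A",
    loci_names=None,
) -> pd.DataFrame:
    """Pool-seq each bin: Poisson depth, binomial allele sampling.

    The pool's true alternative fraction in a bin is the mean allele
    dosage of its members; each read reports the alternative allele with
    probability ``f (1-e) + (1-f) e``.
    """
    L = truth.genotypes.shape[1]
    if loci_names is None:
        loci_names = [f"L{i + 1}" for i in range(L)]
    records = []
    for b in np.unique(bin_of):
        member = bin_of == b
        f = truth.genotypes[member].mean(axis=0) / truth.ploidy
        depth = rng.poisson(depth_mean, size=L)
        p_alt = f * (1 - seq_error) + (1 - f) * seq_error
        alt = rng.binomial(depth, p_alt)
        for j in range(L):
            records.append(
                {
                    "chrom": "2L",
                    "pos": j + 1,
                    "ref": "A",
                    "alt": "T",
                    "locus": loci_names[j],
                    "sample": f"{replicate}{int(b)}",
                    "ref_reads": int(depth[j] - alt[j]),
                    "alt_reads": int(alt[j]),
                }
            )
    return pd.DataFrame(records)


def simulate_experiment(
    config: SimConfig,
    seed: int | None = None,
    include_background: bool = False,
    background_depth: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[SimTruth]]:
    """Run the full design: independent cages per replicate, bin, sequence.

    Returns (counts, bin manifest, per-replicate truth).  With
    ``include_background`` two pools of the whole (un-sorted) replicate-A
    cohort are sequenced as C1/C2 at ``background_depth`` (default twice
    the bin depth, matching the deeper background sequencing).
    """
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)
    rep_names = [chr(ord("A") + i) for i in range(config.replicates)]
    counts_parts, manifest_parts, truths = [], [], []
    for rep in rep_names:
        truth = simulate_population(config, rng)
        manifest, bin_of = bin_individuals(
            truth, config.n_bins, config.bin_scheme, config.window_h, replicate=rep
        )
        counts_parts.append(
            sequence_pools(
                bin_of, truth, config.depth_mean, config.seq_error, rng, replicate=rep
            )
        )
        manifest_parts.append(manifest)
        truths.append(truth)
    if include_background:
        bd = background_depth if background_depth is not None else 2 * config.depth_mean
        whole = np.ones(config.n_individuals, dtype=int)
        for name in ("C1", "C2"):
            bg = sequence_pools(
                whole, truths[0], bd, config.seq_error, rng, replicate=name[0]
            )
            bg["sample"] = name
            counts_parts.append(bg)
    counts = pd.concat(counts_parts, ignore_index=True)
    manifest = pd.concat(manifest_parts, ignore_index=True)
    return counts, manifest, truths


# ---------------------------------------------------------------------------
# individual-level assays
# ---------------------------------------------------------------------------

def simulate_assay(
    effect_f: float,
    effect_m: float,
    n_per_cell: int = 100,
    rate_f: float = 1.0 / 90.0,
    rate_m: float = 1.0 / 60.0,
    seed: int | np.random.Generator | None = None,
    line: str = "sim",
) -> pd.DataFrame:
    """Simulate a knockdown-vs-control survival assay in both sexes.

    ``effect_f``/``effect_m`` are log hazard ratios of knockdown relative
    to control per sex (negative = longer survival).  Baseline exponential
    means default to 90 h (females) and 60 h (males), reflecting the
    longer starvation survival of females.
    """
    if n_per_cell < 2:
        raise ValueError("need at least 2 individuals per cell")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for sex, base_rate, eff in (("F", rate_f, effect_f), ("M", rate_m, effect_m)):
        for group, scale in (("control", 1.0), ("knockdown", np.exp(eff))):
            t = rng.exponential(1.0 / (base_rate * scale), size=n_per_cell)
            for ti in t:
                rows.append(
                    {
                        "line": line,
                        "sex": sex,
                        "group": group,
                        "time": float(ti),
                        "event": True,
                    }
                )
    return pd.DataFrame(rows)


def simulate_qpcr(
    true_knockdown: float | dict,
    noise_sd: float = 0.1,
    n_bio: int = 3,
    n_tech: int = 2,
    seed: int | np.random.Generator | None = None,
    gene: str = "sim",
) -> pd.DataFrame:
    """Simulate a comparative-Ct qPCR table with known knockdown fraction.

    ``true_knockdown`` is the expected relative expression 2^-ddCt of the
    knockdown group (a scalar or a per-sex dict).  Gaussian noise of
    ``noise_sd`` cycles is added to every biological replicate's Ct.
    """
    if not isinstance(true_knockdown, dict):
        true_knockdown = {"F": true_knockdown, "M": true_knockdown}
    for v in true_knockdown.values():
        if not 0 < v <= 1:
            raise ValueError("true_knockdown must lie in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ct_ref = 18.0
    dct_ctl = 4.0  # control target is 4 cycles above the reference gene
    rows = []
    for sex, kd in true_knockdown.items():
        dct_kd = dct_ctl - np.log2(kd)
        for group, dct in (("control", dct_ctl), ("knockdown", dct_kd)):
            for b in range(1, n_bio + 1):
                bio_noise = rng.normal(0.0, noise_sd)
                for t in range(1, n_tech + 1):
                    rows.append(
                        {
                            "gene": gene,
                            "sex": sex,
                            "group": group,
                            "bio_rep": f"b{b}",
                            "tech_rep": f"t{t}",
                            "ct_target": float(ct_ref + dct + bio_noise),
                            "ct_reference": float(ct_ref),
                        }
                    )
    return pd.DataFrame(rows)
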