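"""Generative model for aneuploid Drosophila-like RNA-seq counts.

The simulator emulates bulk RNA-seq of whole larvae across euploid and
aneuploid karyotypes.  Expression of every gene is a product of
multiplicative factors:

* cis gene-dosage: a gene on an arm present in ``c`` copies (normal ``c0``)
  is expressed proportionally, factor ``c / c0``;
* trans inverse-dosage: increasing the dosage of any chromosome arm
  down-regulates the rest of the genome; responsive genes get factor
  ``c0 / c`` per varied arm (2/3 in a trisomy).  On the varied arm itself
  the two effects cancel (3/2 x 2/3 = 1): dosage compensation;
* MSL2 trans-repression: ectopic MSL2 in females assembles the MSL complex
  de novo on the X, sequestering chromatin modifiers and further reducing
  expression of responsive genes genome-wide (default factor 2/3).  Males
  already carry the endogenous complex and are insensitive (factor 1);
* sex bias: sex-biased genes are up-multiplied in their biased sex;
* batch: per-gene log2 offsets drawn per sequencing batch.

Counts are negative-binomial with per-gene dispersion (variance
mu + alpha * mu^2).  The analytic :func:`expected_ratio` is the oracle the
downstream ratio/profile/DE/coexpression stages are validated against.

CPM normalization divides by the library total, so it measures relative
composition: a genome-wide multiplicative shift partly cancels through the
total, and per-gene CPM ratios equal the generative ratios only when the
library mass is approximately invariant across karyotypes.  Observed
aneuploid CPM distributions do peak at the uninflated theoretical ratios
(2/3, 1, 4/9), which is only coherent if most library mass is carried by
dosage-insensitive transcripts.  The default model therefore includes a
small set of high-abundance *stable* genes (perdurant maternal,
structural, and housekeeping-like RNAs whose steady-state levels do not
track zygotic copy number) that hold most of the library mass, anchor the
CPM denominator, and are exempt from cis, trans, and MSL2 effects.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ARMS = ("X", "2L", "2R", "3L", "3R", "4")

#: Desk-scale gene counts per chromosome arm (real arms carry ~2-3.5k genes
#: apiece and the dot chromosome ~100; proportions are kept, scale reduced).
DEFAULT_GENES_PER_ARM = {"X": 900, "2L": 900, "2R": 900, "3L": 900, "3R": 900, "4": 60}

DEFAULT_LIBRARY_SIZE = 5_000_000


# ---------------------------------------------------------------------------
# karyotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Karyotype:
    """Chromosome-arm copy numbers plus sex and MSL2 transgene status."""

    copies_per_arm: tuple  # tuple of (arm, copies), hashable
    sex: str  # "female" | "male"
    msl2_transgene: bool = False

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")
        for arm, c in self.copies_per_arm:
            if arm not in ARMS:
                raise ValueError(f"unknown chromosome arm {arm!r}")
            if c not in (1, 2, 3):
                raise ValueError(f"copy number {c} out of range for arm {arm}")

    def copies(self, arm: str) -> int:
        if arm not in ARMS:
            raise ValueError(f"unknown chromosome arm {arm!r}")
        d = dict(self.copies_per_arm)
        return d.get(arm, normal_copies(arm, self.sex))

    def varied_arms(self) -> list:
        """Arms whose copy number differs from the sex-matched euploid."""
        return [a for a in ARMS if self.copies(a) != normal_copies(a, self.sex)]


def normal_copies(arm: str, sex: str) -> int:
    """Euploid copy number: autosomes 2; X is 2 in females, 1 in males."""
    if arm == "X" and sex == "male":
        return 1
    return 2


def make_karyotype(genotype: str) -> Karyotype:
    """Build a :class:`Karyotype` from one of the study's genotype labels."""
    try:
        return GENOTYPES[genotype]
    except KeyError:
        raise ValueError(
            f"unknown genotype {genotype!r}; known: {sorted(GENOTYPES)}"
        ) from None


GENOTYPES = {
    "diploid_female": Karyotype((), "female"),
    "diploid_male": Karyotype((), "male"),
    "trisomy2L_female": Karyotype((("2L", 3),), "female"),
    "trisomy2L_male": Karyotype((("2L", 3),), "male"),
    "msl2_trisomy2L_female": Karyotype((("2L", 3),), "female", msl2_transgene=True),
    "msl2_trisomy2L_male": Karyotype((("2L", 3),), "male", msl2_transgene=True),
    "metafemale": Karyotype((("X", 3),), "female"),
    "msl2_metafemale": Karyotype((("X", 3),), "female", msl2_transgene=True),
}


def genotype_label(kar: Karyotype) -> str:
    for name, k in GENOTYPES.items():
        if k == kar:
            return name
    parts = [f"{a}x{c}" for a, c in kar.copies_per_arm]
    return ("msl2_" if kar.msl2_transgene else "") + "_".join(parts or ["diploid"]) + "_" + kar.sex


# ---------------------------------------------------------------------------
# genome annotation
# ---------------------------------------------------------------------------

def build_genome(
    n_genes_per_arm: dict | None = None,
    frac_sex_biased: float = 0.15,
    frac_tf: float = 0.05,
    frac_responsive: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a gene annotation table with known truth labels.

    Returns a DataFrame with columns ``gene_id``, ``arm``, ``position``
    (ordinal rank within arm), ``sex_bias_truth`` (female/male/none),
    ``is_tf``, ``responsive``.  Label quotas are exact (``round(frac * n)``
    genes per label) and assignment is deterministic for a fixed seed.
    Sex-biased genes split evenly between female- and male-biased (odd
    remainder goes to female).
    """
    if n_genes_per_arm is None:
        n_genes_per_arm = dict(DEFAULT_GENES_PER_ARM)
    for arm, n in n_genes_per_arm.items():
        if arm not in ARMS:
            raise ValueError(f"unknown chromosome arm {arm!r}")
        if n < 1:
            raise ValueError(f"gene count for arm {arm} must be >= 1, got {n}")
    for name, frac in (("frac_sex_biased", frac_sex_biased),
                       ("frac_tf", frac_tf),
                       ("frac_responsive", frac_responsive)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")

    rows = []
    for arm in ARMS:  # fixed arm order -> deterministic layout
        if arm not in n_genes_per_arm:
            continue
        n = n_genes_per_arm[arm]
        for i in range(n):
            rows.append((f"g{arm}_{i:05d}", arm, i))
    ann = pd.DataFrame(rows, columns=["gene_id", "arm", "position"])
    n_total = len(ann)

    rng = np.random.default_rng(seed)
    ann["sex_bias_truth"] = "none"
    n_sb = int(round(frac_sex_biased * n_total))
    sb_idx = rng.choice(n_total, size=n_sb, replace=False)
    n_female = n_sb - n_sb // 2
    ann.loc[sb_idx[:n_female], "sex_bias_truth"] = "female"
    ann.loc[sb_idx[n_female:], "sex_bias_truth"] = "male"

    ann["is_tf"] = False
    n_tf = int(round(frac_tf * n_total))
    ann.loc[rng.choice(n_total, size=n_tf, replace=False), "is_tf"] = True

    ann["responsive"] = False
    n_resp = int(round(frac_responsive * n_total))
    ann.loc[rng.choice(n_total, size=n_resp, replace=False), "responsive"] = True

    return ann


# ---------------------------------------------------------------------------
# effect model
# ---------------------------------------------------------------------------

@dataclass
class EffectModel:
    """Per-gene generative parameters and the global effect sizes.

    ``baseline_mean`` is on CPM scale; NB variance is mu + dispersion*mu^2.
    ``batch_log2_offset`` maps batch id -> per-gene log2 offset array.
    ``inverse_enabled`` switches the trans inverse-dosage response off for
    dosage-effect-only simulations.
    """

    baseline_mean: np.ndarray
    dispersion: np.ndarray
    msl2_factor: float = 2.0 / 3.0
    sex_bias_mult: float = 4.0
    inverse_enabled: bool = True
    batch_log2_offset: dict = field(default_factory=dict)
    stable: np.ndarray | None = None  # dosage-insensitive mass anchor genes

    def __post_init__(self):
        self.baseline_mean = np.asarray(self.baseline_mean, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        if self.stable is None:
            self.stable = np.zeros(self.baseline_mean.shape, dtype=bool)
        else:
            self.stable = np.asarray(self.stable, dtype=bool)
        if self.baseline_mean.shape != self.dispersion.shape:
            raise ValueError("baseline_mean and dispersion must align")
        if self.stable.shape != self.baseline_mean.shape:
            raise ValueError("stable mask must align with baseline_mean")
        if np.any(self.baseline_mean < 0):
            raise ValueError("baseline means must be non-negative")
        if np.any(self.dispersion < 0):
            raise ValueError("dispersions must be non-negative")
        if not 0 < self.msl2_factor <= 1:
            raise ValueError("msl2_factor must be in (0, 1]")
        if self.sex_bias_mult <= 0:
            raise ValueError("sex_bias_mult must be positive")

    @classmethod
    def default(
        cls,
        annotation: pd.DataFrame,
        seed: int = 0,
        mean_log: float = 3.0,
        sd_log: float = 1.5,
        disp_shape: float = 2.0,
        disp_scale: float = 0.005,
        batches: tuple = (),
        batch_loc: float = 0.0,
        batch_scale: float = 0.3,
        stable_mass: float = 0.96,
        n_stable: int = 150,
        stable_dispersion: float = 0.005,
        **kwargs,
    ) -> "EffectModel":
        """Draw per-gene baselines (log-normal, CPM scale) and dispersions
        (gamma, mean ``disp_shape*disp_scale``); optionally per-batch
        per-gene log2 offsets ~ N(batch_loc, batch_scale).

        ``n_stable`` unresponsive, non-sex-biased genes are promoted to the
        stable high-abundance compartment carrying ``stable_mass`` of the
        expected library, with low dispersion (see the module docstring for
        why CPM-space ratio recovery requires this mass anchor).
        """
        rng = np.random.default_rng(seed)
        n = len(annotation)
        baseline = rng.lognormal(mean_log, sd_log, size=n)
        disp = rng.gamma(disp_shape, disp_scale, size=n)
        stable = np.zeros(n, dtype=bool)
        if n_stable > 0 and stable_mass > 0:
            eligible = np.flatnonzero(
                (~annotation["responsive"].to_numpy(dtype=bool))
                & (annotation["sex_bias_truth"].to_numpy() == "none")
            )
            if len(eligible) < n_stable:
                raise ValueError(
                    f"only {len(eligible)} genes eligible for the stable "
                    f"compartment, need {n_stable}"
                )
            stable[rng.choice(eligible, size=n_stable, replace=False)] = True
            regular_mass = baseline[~stable].sum()
            w = rng.lognormal(0.0, 0.5, size=n_stable)
            baseline[stable] = (
                w / w.sum() * regular_mass * stable_mass / (1.0 - stable_mass)
            )
            disp[stable] = stable_dispersion
        offsets = {}
        for i, b in enumerate(batches):
            if i == 0:
                # first batch is the reference: no offset
                offsets[b] = np.zeros(n)
                continue
            # batch-keyed sub-stream so adding a batch never reshuffles others
            h = int.from_bytes(hashlib.sha256(str(b).encode()).digest()[:4], "big")
            brng = np.random.default_rng(np.random.SeedSequence([seed, h]))
            offsets[b] = brng.normal(batch_loc, batch_scale, size=n)
        return cls(baseline, disp, batch_log2_offset=offsets, stable=stable, **kwargs)


def _effect_factors(annotation: pd.DataFrame, kar: Karyotype, model: EffectModel) -> np.ndarray:
    """Multiplicative expression factor per gene under ``kar`` (no batch)."""
    arms = annotation["arm"].to_numpy()
    unknown = set(arms) - set(ARMS)
    if unknown:
        raise ValueError(f"unknown chromosome arm(s) {sorted(unknown)}")
    responsive = annotation["responsive"].to_numpy(dtype=bool)
    f = np.ones(len(annotation))
    for arm in kar.varied_arms():
        c = kar.copies(arm)
        c0 = normal_copies(arm, kar.sex)
        f[arms == arm] *= c / c0            # cis gene-dosage
        if model.inverse_enabled:
            f[responsive] *= c0 / c         # trans inverse-dosage
    if kar.msl2_transgene and kar.sex == "female":
        f[responsive] *= model.msl2_factor
    bias = annotation["sex_bias_truth"].to_numpy()
    f[bias == kar.sex] *= model.sex_bias_mult
    f[model.stable] = 1.0  # mass-anchor genes ignore all dosage effects
    return f


def expected_expression(annotation: pd.DataFrame, kar: Karyotype, model: EffectModel) -> np.ndarray:
    """Expected CPM-scale expression per gene under a karyotype."""
    return model.baseline_mean * _effect_factors(annotation, kar, model)


def expected_ratios(
    annotation: pd.DataFrame,
    experimental: Karyotype,
    control: Karyotype,
    model: EffectModel,
) -> np.ndarray:
    """Analytic experimental/control expression ratio per gene.

    This is the oracle the full count-level pipeline must recover: e.g.
    responsive varied-arm genes in a trisomy give 3/2 x 2/3 = 1 (dosage
    compensation) and responsive trans genes give 2/3.
    """
    return _effect_factors(annotation, experimental, model) / _effect_factors(
        annotation, control, model
    )


def expected_ratio(gene: pd.Series, experimental: Karyotype, control: Karyotype,
                   model: EffectModel) -> float:
    """Scalar :func:`expected_ratios` for a single annotation row.

    The per-gene baseline cancels in the ratio, so only the gene's arm and
    labels plus the model's global effect sizes enter.
    """
    sub = gene.to_frame().T
    m = EffectModel(
        baseline_mean=np.ones(1),
        dispersion=np.zeros(1),
        msl2_factor=model.msl2_factor,
        sex_bias_mult=model.sex_bias_mult,
        inverse_enabled=model.inverse_enabled,
    )
    return float(expected_ratios(sub, experimental, control, m)[0])


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer gene x sample counts plus the sample sheet."""

    counts: pd.DataFrame  # genes x samples, index = gene_id
    samples: pd.DataFrame  # index = sample_id; genotype, sex, batch, replicate

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns and sample sheet must align")


def simulate_counts(
    annotation: pd.DataFrame,
    model: EffectModel,
    designs: list,
    library_size: int = DEFAULT_LIBRARY_SIZE,
    seed: int = 0,
) -> CountMatrix:
    """Draw NB counts for a list of designs.

    Each design is ``(karyotype_or_genotype_label, n_replicates, batch_id)``.
    Mean counts are ``baseline_cpm * effect factors * 2^batch_offset *
    library_size / 1e6``; a fixed seed reproduces the matrix bit for bit.
    """
    if not designs:
        raise ValueError("design list must not be empty")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if len(model.baseline_mean) != len(annotation):
        raise ValueError("model and annotation must have the same gene count")

    rng = np.random.default_rng(seed)
    cols, meta = [], []
    data = {}
    for kar, n_reps, batch in designs:
        if isinstance(kar, str):
            label, kar = kar, make_karyotype(kar)
        else:
            label = genotype_label(kar)
        if n_reps < 1:
            raise ValueError("n_replicates must be >= 1")
        mu = expected_expression(annotation, kar, model) * (library_size / 1e6)
        off = model.batch_log2_offset.get(batch)
        if off is not None:
            mu = mu * np.exp2(off)
        for r in range(1, n_reps + 1):
            sid = f"{label}.b{batch}.r{r}"
            data[sid] = _nb_draw(rng, mu, model.dispersion)
            cols.append(sid)
            meta.append((sid, label, kar.sex, batch, r))
    counts = pd.DataFrame(data, index=annotation["gene_id"].to_numpy())
    counts.index.name = "gene_id"
    samples = pd.DataFrame(
        meta, columns=["sample_id", "genotype", "sex", "batch", "replicate"]
    ).set_index("sample_id")
    return CountMatrix(counts, samples)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, var = mu + alpha mu^2); alpha ~ 0 falls back to Poisson."""
    out = np.zeros(len(mu), dtype=np.int64)
    pois = alpha < 1e-8
    nz = mu > 0
    out[pois & nz] = rng.poisson(mu[pois & nz])
    sel = (~pois) & nz
    if sel.any():
        n = 1.0 / alpha[sel]
        p = n / (n + mu[sel])
        out[sel] = rng.negative_binomial(n, p)
    return out
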