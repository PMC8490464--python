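"""Canonical in-silico study: the default simulated conditions under which
the pipeline is expected to recover the theoretical dosage-effect ratios.

The study mirrors the autosomal-aneuploidy design: trisomy-2L females,
MSL2-transgene trisomy-2L females, and matched diploid females, three
replicates each, default effect model, library parameter 5e6.  The full
pipeline (prefilter, CPM, replicate averaging, nonpositive filter, ratio
binning at width 0.05) is then asked for the modal bin centers:

* trans genes (X + other autosomes), trisomy vs diploid  -> 2/3 peak
* varied-arm (2L) genes, trisomy vs diploid              -> 1.0 peak
  (dosage compensation; 3/2 cis x 2/3 inverse)
* varied-arm genes with the inverse response disabled    -> 3/2 peak
* X genes, MSL2-trisomy vs diploid                       -> 4/9 ~ 0.45 peak
* varied-arm genes, MSL2-trisomy vs diploid              -> 2/3 peak
"""

from __future__ import annotations

import numpy as np

from .preprocess import preprocess_counts
from .ratios import bin_distribution, compute_ratios, modal_peak
from .synthetic import EffectModel, build_genome, simulate_counts


def _derive_seeds(seed: int) -> tuple:
    ss = np.random.SeedSequence(seed)
    return tuple(int(s) % (2**31) for s in ss.generate_state(4))


def trisomy_study_modal_peaks(seed: int = 0) -> dict:
    """Run the canonical simulated study end to end.

    Returns modal bin centers keyed ``trans_trisomy``, ``varied_trisomy``,
    ``varied_dosage_only``, ``x_msl2``, ``varied_msl2``, plus the number of
    genes entering each distribution under ``n_*`` keys.
    """
    s_genome, s_model, s_counts, s_counts2 = _derive_seeds(seed)
    ann = build_genome(seed=s_genome)
    model = EffectModel.default(ann, seed=s_model)
    cm = simulate_counts(
        ann,
        model,
        [("trisomy2L_female", 3, 1), ("diploid_female", 3, 1),
         ("msl2_trisomy2L_female", 3, 1)],
        library_size=5_000_000,
        seed=s_counts,
    )
    means = preprocess_counts(cm)

    out = {}
    tri = compute_ratios(means, "trisomy2L_female", "diploid_female", ann, "2L")
    trans = tri[tri.chrom_class != "varied_arm"]
    varied = tri[tri.chrom_class == "varied_arm"]
    out["trans_trisomy"] = modal_peak(bin_distribution(trans))
    out["n_trans_trisomy"] = len(trans)
    out["varied_trisomy"] = modal_peak(bin_distribution(varied))
    out["n_varied_trisomy"] = len(varied)

    msl = compute_ratios(means, "msl2_trisomy2L_female", "diploid_female", ann, "2L")
    x_genes = msl[msl.chrom_class == "X"]
    varied_msl = msl[msl.chrom_class == "varied_arm"]
    out["x_msl2"] = modal_peak(bin_distribution(x_genes))
    out["n_x_msl2"] = len(x_genes)
    out["varied_msl2"] = modal_peak(bin_distribution(varied_msl))
    out["n_varied_msl2"] = len(varied_msl)

    # dosage-effect-only variant: trans inverse response switched off
    model_cis = EffectModel.default(ann, seed=s_model, inverse_enabled=False)
    cm2 = simulate_counts(
        ann,
        model_cis,
        [("trisomy2L_female", 3, 1), ("diploid_female", 3, 1)],
        library_size=5_000_000,
        seed=s_counts2,
    )
    means2 = preprocess_counts(cm2)
    tab2 = compute_ratios(means2, "trisomy2L_female", "diploid_female", ann, "2L")
    varied2 = tab2[tab2.chrom_class == "varied_arm"]
    out["varied_dosage_only"] = modal_peak(bin_distribution(varied2))
    out["n_varied_dosage_only"] = len(varied2)
    return out
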