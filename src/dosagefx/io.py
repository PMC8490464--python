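"""Plain-text interchange: count TSV, sample sheet, annotation, YAML configs."""

from __future__ import annotations

import pandas as pd
import yaml

from .synthetic import CountMatrix


def write_counts(cm: CountMatrix, counts_path, samples_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.samples.to_csv(samples_path, sep="\t")


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    samples.index = samples.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CountMatrix(counts, samples.loc[counts.columns])


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_design_config(path) -> list:
    """YAML design: list of {genotype, replicates, batch} entries."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    designs = []
    for entry in cfg["design"]:
        designs.append(
            (entry["genotype"], int(entry.get("replicates", 3)), entry.get("batch", 1))
        )
    return designs
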