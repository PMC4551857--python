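"""Loading, probe summarization, filtering, and normalization of expression data.

The processing chain mirrors standard microarray/RNA-seq preprocessing after
vendor-side background correction: probe-level filtering against negative
controls, summarization of probes to gene identifiers by averaging (probes
matching multiple genes are discarded), and per-sample total-signal
normalization. The chain is probe-filter → summarize → normalize, and each
step is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_probe_map",
    "summarize_probes",
    "filter_below_negative_controls",
    "normalize_total_signal",
]


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix.

    Parameters
    ----------
    data
        DataFrame indexed by unique gene identifiers with unique sample
        identifiers as columns; values numeric, no missing entries.
    normalized
        Whether per-sample total-signal normalization has been applied.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        _validate_frame(self.data, what="expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def zero_variance_genes(self) -> list[str]:
        """Genes whose values are constant across samples (undefined correlation)."""
        v = self.values
        mask = np.ptp(v, axis=1) == 0
        return [g for g, m in zip(self.gene_ids, mask) if m]


def _validate_frame(df: pd.DataFrame, what: str) -> None:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers in {what}: {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers in {what}: {dups[:5]}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in {what} for rows: {bad[:5]}")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a TSV matrix: first column identifiers, header row of sample ids.

    Missing values are rejected, not imputed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _validate_frame(df, what=str(path))
    return df.astype(float)


def write_matrix_tsv(df: pd.DataFrame | ExpressionMatrix, path, id_label: str = "gene_id") -> None:
    if isinstance(df, ExpressionMatrix):
        df = df.data
    df.to_csv(path, sep="\t", index_label=id_label)


def read_probe_map(path) -> dict[str, tuple[str, ...]]:
    """Read a two-column TSV (probe, comma-separated gene list).

    Every probe must appear exactly once.
    """
    mapping: dict[str, tuple[str, ...]] = {}
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"probe map {path} needs two columns (probe, genes)")
    for probe, genes in zip(df.iloc[:, 0], df.iloc[:, 1]):
        probe = str(probe)
        if probe in mapping:
            raise ValueError(f"probe {probe!r} appears more than once in the map")
        mapping[probe] = tuple(g.strip() for g in str(genes).split(",") if g.strip())
    return mapping


def summarize_probes(
    probe_matrix: pd.DataFrame, probe_map: dict[str, tuple[str, ...]]
) -> ExpressionMatrix:
    """Summarize a probe × sample matrix to gene level by averaging probes.

    Probes mapping to more than one gene are excluded entirely; each gene's
    expression is the arithmetic mean of its retained probes. Genes with no
    surviving probe are absent from the output.

    Raises
    ------
    KeyError
        If a probe in the matrix has no entry in ``probe_map``.
    """
    _validate_frame(probe_matrix, what="probe matrix")
    missing = [p for p in probe_matrix.index if p not in probe_map]
    if missing:
        raise KeyError(f"probes absent from probe map: {missing[:5]}")
    gene_to_probes: dict[str, list[str]] = {}
    for probe in probe_matrix.index:
        genes = probe_map[probe]
        if len(genes) != 1:
            continue  # multi-mapping (or unmapped) probes are dropped
        gene_to_probes.setdefault(genes[0], []).append(probe)
    rows = {
        gene: probe_matrix.loc[probes].mean(axis=0)
        for gene, probes in gene_to_probes.items()
    }
    out = pd.DataFrame(rows).T
    if out.empty:
        out = pd.DataFrame(columns=probe_matrix.columns)
    out.index.name = "gene_id"
    return ExpressionMatrix(out.sort_index())


def filter_below_negative_controls(
    probe_matrix: pd.DataFrame, negative_control_ids
) -> pd.DataFrame:
    """Remove probes that fall below the negative-control mean in every sample.

    A probe is removed iff its value is strictly below the per-sample mean of
    the negative-control probes in *every* sample (a probe exactly equal to
    the control mean is retained). Control rows themselves are removed from
    the output.
    """
    controls = [c for c in negative_control_ids if c in probe_matrix.index]
    if not controls:
        raise ValueError("no negative-control probes found in the matrix")
    control_mean = probe_matrix.loc[controls].mean(axis=0)
    rest = probe_matrix.drop(index=controls)
    below_everywhere = (rest.lt(control_mean, axis=1)).all(axis=1)
    return rest.loc[~below_everywhere]


def normalize_total_signal(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample column by its total signal.

    After normalization every column sums to 1; the operation is idempotent
    up to floating-point tolerance. Columns with zero or negative totals are
    rejected by name.
    """
    totals = matrix.data.sum(axis=0)
    bad = totals[totals <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive total signal for sample(s): {list(bad.index)[:5]}"
        )
    return ExpressionMatrix(matrix.data.div(totals, axis=1), normalized=True)
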