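"""Tabular input/output, validation and cohort handling.

All matrices are tab-separated text with a header row of sample ids.
The aCGH matrix carries probe identifiers plus genomic coordinates, the
expression matrix carries gene identifiers, and a mapping table ties each
probe to exactly one gene.  Probes are kept in genomic order (chromosome,
then base-pair position) because the baseline copy-number means follow a
first-order Markov chain along the chromosome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "load_matrices",
    "summarize_cohort",
    "split_train_test",
    "write_results",
    "natural_chrom_key",
]

MISSING_TOKENS = {"NA", "NaN", "nan", ""}


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key ordering chromosome names naturally (chr2 < chr10 < chrX)."""
    parts = re.split(r"(\d+)", str(chrom))
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass
class Dataset:
    """Validated, genomically ordered container for one matched cohort.

    Attributes
    ----------
    Y : pandas.DataFrame
        Probe-level aCGH log2 ratios, probes x samples, in genomic order.
    Z : pandas.DataFrame
        Gene-level log2 expression, genes x samples (same sample columns).
    probe_info : pandas.DataFrame
        Indexed by probe_id with columns ``chromosome``, ``position``,
        ``gene_id``; same order as ``Y``.
    covariates : pandas.DataFrame
        Indexed by sample_id with integer column ``x`` (1 = triple negative)
        and float column ``u`` (pCR outcome; NaN = missing).
    dropped_probes : list of str
        Probes present in the aCGH matrix but absent from the mapping,
        removed during loading.
    """

    Y: pd.DataFrame
    Z: pd.DataFrame
    probe_info: pd.DataFrame
    covariates: pd.DataFrame
    dropped_probes: list = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- structural accessors used by the sampler ------------------------
    @property
    def n_probes(self) -> int:
        return self.Y.shape[0]

    @property
    def n_genes(self) -> int:
        return self.Z.shape[0]

    @property
    def n_samples(self) -> int:
        return self.Y.shape[1]

    @property
    def gene_of(self) -> np.ndarray:
        """Integer gene index of every probe (position in ``Z.index``)."""
        lookup = {g: i for i, g in enumerate(self.Z.index)}
        return np.array([lookup[g] for g in self.probe_info["gene_id"]])

    @property
    def chain_start(self) -> np.ndarray:
        """Boolean mask: probe starts a new Markov chain (chromosome change)."""
        chroms = self.probe_info["chromosome"].to_numpy()
        start = np.ones(len(chroms), dtype=bool)
        start[1:] = chroms[1:] != chroms[:-1]
        return start

    def validate(self) -> None:
        if self.Y.index.duplicated().any():
            dups = self.Y.index[self.Y.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated probe_id(s): {dups}")
        if self.Z.index.duplicated().any():
            dups = self.Z.index[self.Z.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene_id(s): {dups}")
        if list(self.Y.columns) != list(self.Z.columns):
            raise ValueError("sample columns of aCGH and expression matrices differ")
        if list(self.Y.columns) != list(self.covariates.index):
            raise ValueError("covariate sample ids do not match matrix columns")
        if not self.probe_info.index.equals(self.Y.index):
            raise ValueError("probe_info must be aligned with Y")
        unknown = set(self.probe_info["gene_id"]) - set(self.Z.index)
        if unknown:
            raise ValueError(f"probes mapped to unknown gene(s): {sorted(unknown)}")
        orphan = set(self.Z.index) - set(self.probe_info["gene_id"])
        if orphan:
            raise ValueError(f"gene(s) without any probe: {sorted(orphan)}")
        if (self.probe_info["position"].to_numpy() < 0).any():
            raise ValueError("probe positions must be non-negative")
        if not set(np.unique(self.covariates["x"])) <= {0, 1}:
            raise ValueError("covariate x must be binary (0/1)")
        u = self.covariates["u"].to_numpy(dtype=float)
        obs = u[~np.isnan(u)]
        if not set(np.unique(obs)) <= {0.0, 1.0}:
            raise ValueError("outcome u must be 0, 1 or missing")


def _read_matrix(path, id_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    first = df.columns[0]
    if first != id_col:
        df = df.rename(columns={first: id_col})
    df = df.set_index(id_col)
    return df.astype(float)


def load_matrices(probe_path, expr_path, map_path, covar_path) -> Dataset:
    """Read the four TSV inputs and assemble a validated :class:`Dataset`.

    Probes absent from the mapping are dropped (reported in
    ``Dataset.dropped_probes``); probes mapped to a gene that is not in the
    expression matrix raise an error naming the offenders.  Probes are
    sorted by (chromosome, position, probe_id) with natural chromosome
    ordering; the Markov chain over baseline means restarts at every
    chromosome boundary.
    """
    Y = _read_matrix(probe_path, "probe_id")
    Z = _read_matrix(expr_path, "gene_id")
    if Y.index.duplicated().any():
        dups = Y.index[Y.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated probe_id(s): {dups}")

    mapping = pd.read_csv(map_path, sep="\t", dtype=str)
    need = {"probe_id", "gene_id", "chromosome", "position"}
    if not need <= set(mapping.columns):
        raise ValueError(f"mapping file must have columns {sorted(need)}")
    if mapping["probe_id"].duplicated().any():
        dups = mapping.loc[mapping["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"probe mapped more than once: {dups}")
    mapping = mapping.set_index("probe_id")
    mapping["position"] = mapping["position"].astype(int)

    dropped = [p for p in Y.index if p not in mapping.index]
    Y = Y.drop(index=dropped)
    info = mapping.loc[Y.index, ["chromosome", "position", "gene_id"]]

    order = sorted(
        range(len(Y)),
        key=lambda i: (
            natural_chrom_key(info["chromosome"].iloc[i]),
            info["position"].iloc[i],
            str(Y.index[i]),
        ),
    )
    Y = Y.iloc[order]
    info = info.iloc[order]

    covars = pd.read_csv(
        covar_path, sep="\t", dtype={"sample_id": str},
        na_values=sorted(MISSING_TOKENS), keep_default_na=True,
    ).set_index("sample_id")
    covars["x"] = covars["x"].astype(int)
    covars["u"] = covars["u"].astype(float)

    if set(covars.index) != set(Y.columns):
        raise ValueError("covariate sample set does not match matrix columns")
    covars = covars.loc[list(Y.columns)]

    # keep only genes that retained at least one probe after the drop
    genes_with_probes = pd.unique(info["gene_id"])
    missing_genes = [g for g in genes_with_probes if g not in Z.index]
    if missing_genes:
        raise ValueError(f"probes mapped to unknown gene(s): {missing_genes}")
    Z = Z.loc[[g for g in Z.index if g in set(genes_with_probes)]]

    return Dataset(Y=Y, Z=Z, probe_info=info, covariates=covars,
                   dropped_probes=dropped)


def summarize_cohort(covariates: pd.DataFrame) -> pd.DataFrame:
    """Contingency table of pCR status by subgroup, with margins.

    Rows: positive / negative / missing pCR plus ``TOT``; columns: ``TN``
    (x = 1), ``other`` (x = 0) plus ``TOT``.
    """
    rows = ["positive", "negative", "missing"]
    cols = ["TN", "other"]
    table = pd.DataFrame(0, index=rows + ["TOT"], columns=cols + ["TOT"])
    x = covariates["x"].to_numpy()
    u = covariates["u"].to_numpy(dtype=float)
    for ci, xv in ((0, 1), (1, 0)):
        in_group = x == xv
        table.iloc[0, ci] = int(np.sum(in_group & (u == 1)))
        table.iloc[1, ci] = int(np.sum(in_group & (u == 0)))
        table.iloc[2, ci] = int(np.sum(in_group & np.isnan(u)))
    table["TOT"] = table[cols].sum(axis=1)
    table.loc["TOT"] = table.iloc[:3].sum(axis=0)
    return table


def split_train_test(covariates: pd.DataFrame, test_size: int, seed: int):
    """Constrained train/test partition of the patients with observed pCR.

    The test set is forced to be balanced: ``test_size / 2`` positive and
    ``test_size / 2`` negative pCR patients, drawn uniformly at random
    within each stratum.  The training set is everyone else with an
    observed outcome, which therefore keeps (as closely as integer counts
    allow) the outcome proportions of the full cohort.
    """
    if test_size % 2 != 0:
        raise ValueError("test_size must be even (balanced test set)")
    u = covariates["u"]
    known = covariates[u.notna()]
    pos = known.index[known["u"] == 1].to_numpy()
    neg = known.index[known["u"] == 0].to_numpy()
    half = test_size // 2
    if len(pos) < half:
        raise ValueError(
            f"need {half} positive-pCR patients for the test set, have {len(pos)}")
    if len(neg) < half:
        raise ValueError(
            f"need {half} negative-pCR patients for the test set, have {len(neg)}")
    rng = np.random.default_rng(seed)
    test = np.concatenate([
        rng.choice(pos, size=half, replace=False),
        rng.choice(neg, size=half, replace=False),
    ])
    test_set = set(test)
    train = [s for s in known.index if s not in test_set]
    return list(train), list(test)


def write_results(selections, pcr_probs, out_dir) -> dict:
    """Write gene lists and per-patient predictive probabilities as TSV.

    Parameters
    ----------
    selections : iterable of GeneSelection (may be empty)
    pcr_probs : pandas.Series or None
        Posterior predictive P(pCR = 1) indexed by sample id.
    out_dir : path

    Returns the mapping of logical name -> written file path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    rows = []
    for sel in selections or []:
        for rank, (gene, prob) in enumerate(
                zip(sel.gene_ids, sel.posterior_probs), start=1):
            rows.append({
                "list_label": sel.list_label, "gene_id": gene,
                "posterior_prob": float(prob), "rank": rank,
            })
    genes = pd.DataFrame(rows, columns=["list_label", "gene_id",
                                        "posterior_prob", "rank"])
    gene_path = out_dir / "gene_lists.tsv"
    genes.to_csv(gene_path, sep="\t", index=False)
    written["gene_lists"] = gene_path

    if pcr_probs is not None:
        pred_path = out_dir / "pcr_probabilities.tsv"
        pd.DataFrame({"sample_id": pcr_probs.index,
                      "p_pcr": pcr_probs.to_numpy()}).to_csv(
            pred_path, sep="\t", index=False)
        written["pcr_probabilities"] = pred_path
    return written


def write_dataset(data: Dataset, out_dir) -> dict:
    """Write a :class:`Dataset` back to the four standard TSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "probes": out_dir / "acgh_log2ratios.tsv",
        "expr": out_dir / "expression_log2.tsv",
        "map": out_dir / "probe_gene_map.tsv",
        "covars": out_dir / "covariates.tsv",
    }
    data.Y.rename_axis("probe_id").to_csv(paths["probes"], sep="\t")
    data.Z.rename_axis("gene_id").to_csv(paths["expr"], sep="\t")
    data.probe_info.rename_axis("probe_id").reset_index()[
        ["probe_id", "gene_id", "chromosome", "position"]
    ].to_csv(paths["map"], sep="\t", index=False)
    cov = data.covariates.rename_axis("sample_id").reset_index()
    cov.to_csv(paths["covars"], sep="\t", index=False, na_rep="NA")
    return paths
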