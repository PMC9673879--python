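"""Domain containers and I/O for microbe-drug association data.

The central object is :class:`AssociationDataset`: a binary bipartite
adjacency matrix ``A`` (rows = drugs, columns = microbes) together with id
registries and optional side information (drug-disease and microbe-disease
association matrices, and externally supplied drug chemical-structure and
microbe functional similarity matrices).

Association lists are exchanged as 2-column TSV/CSV files with a header;
dense matrices as headered TSV with row ids in the first column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssociationDataset",
    "read_association_list",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_score_matrix",
    "read_score_matrix",
]


def _check_binary(M: np.ndarray, name: str) -> None:
    if not np.isin(M, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")


def _check_no_duplicates(ids: list[str], name: str) -> None:
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate identifiers in {name}")


@dataclass
class AssociationDataset:
    """Known microbe-drug associations plus optional side matrices.

    Parameters
    ----------
    drug_ids, microbe_ids
        Ordered identifier registries; row/column order of ``A``.
    A
        Binary matrix of shape ``(n_drugs, n_microbes)``; ``A[i, j] = 1``
        iff drug ``i`` is known to associate with microbe ``j``.
    drug_disease, microbe_disease
        Optional binary association matrices against a shared disease axis
        (``disease_ids``); drugs/microbes without disease links get all-zero
        rows.
    drug_chemical_sim, microbe_functional_sim
        Optional externally computed square similarity matrices (e.g.
        SIMCOMP2-style chemical similarity, gene-neighbourhood functional
        similarity).
    """

    drug_ids: list[str]
    microbe_ids: list[str]
    A: np.ndarray
    disease_ids: list[str] = field(default_factory=list)
    drug_disease: np.ndarray | None = None
    microbe_disease: np.ndarray | None = None
    drug_chemical_sim: np.ndarray | None = None
    microbe_functional_sim: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        _check_no_duplicates(self.drug_ids, "drug_ids")
        _check_no_duplicates(self.microbe_ids, "microbe_ids")
        if self.A.shape != (len(self.drug_ids), len(self.microbe_ids)):
            raise ValueError(
                f"A has shape {self.A.shape}, expected "
                f"({len(self.drug_ids)}, {len(self.microbe_ids)})"
            )
        _check_binary(self.A, "A")
        n_d = len(self.disease_ids)
        for name, M, rows in (
            ("drug_disease", self.drug_disease, self.n_drugs),
            ("microbe_disease", self.microbe_disease, self.n_microbes),
        ):
            if M is not None:
                M = np.asarray(M, dtype=float)
                setattr(self, name, M)
                if M.shape != (rows, n_d):
                    raise ValueError(
                        f"{name} has shape {M.shape}, expected ({rows}, {n_d})"
                    )
                _check_binary(M, name)
        for name, M, n in (
            ("drug_chemical_sim", self.drug_chemical_sim, self.n_drugs),
            ("microbe_functional_sim", self.microbe_functional_sim, self.n_microbes),
        ):
            if M is not None:
                M = np.asarray(M, dtype=float)
                setattr(self, name, M)
                if M.shape != (n, n):
                    raise ValueError(f"{name} must be {n}x{n}, got {M.shape}")
                if not np.isfinite(M).all():
                    raise ValueError(f"{name} contains non-finite entries")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_microbes(self) -> int:
        return len(self.microbe_ids)

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AssociationDataset({self.n_drugs} drugs x {self.n_microbes} "
            f"microbes, {self.n_associations} associations)"
        )


def read_association_list(
    path,
    format: str | None = None,
    drug_order: list[str] | None = None,
    microbe_order: list[str] | None = None,
) -> AssociationDataset:
    """Read a (drug, microbe) pair list into an :class:`AssociationDataset`.

    The file must have a header and at least two columns (drug id, microbe
    id); a third column, if present, is ignored. Rows and columns of the
    adjacency matrix follow first-appearance order unless explicit id orders
    are supplied. Duplicate pairs collapse to a single association.
    """
    sep = _infer_sep(path, format)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, header=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty association file: {path}") from exc
    if df.shape[1] < 2:
        raise ValueError(
            f"association file {path} needs >=2 columns, found {df.shape[1]}"
        )
    bad = df.index[df.iloc[:, 0].isna() | df.iloc[:, 1].isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"malformed association row at line {bad[0] + 2} of {path}")
    if df.empty:
        raise ValueError(f"association file {path} contains no pairs")

    drugs = df.iloc[:, 0].tolist()
    microbes = df.iloc[:, 1].tolist()
    drug_ids = drug_order if drug_order is not None else list(dict.fromkeys(drugs))
    microbe_ids = (
        microbe_order if microbe_order is not None else list(dict.fromkeys(microbes))
    )
    d_index = {d: i for i, d in enumerate(drug_ids)}
    m_index = {m: j for j, m in enumerate(microbe_ids)}
    A = np.zeros((len(drug_ids), len(microbe_ids)))
    for d, m in zip(drugs, microbes):
        if d not in d_index:
            raise ValueError(f"drug id {d!r} absent from supplied drug order")
        if m not in m_index:
            raise ValueError(f"microbe id {m!r} absent from supplied microbe order")
        A[d_index[d], m_index[m]] = 1.0
    return AssociationDataset(drug_ids=drug_ids, microbe_ids=microbe_ids, A=A)


def attach_disease_associations(
    dataset: AssociationDataset,
    drug_disease_path=None,
    microbe_disease_path=None,
    format: str | None = None,
) -> AssociationDataset:
    """Load (drug, disease) and (microbe, disease) lists onto a dataset.

    The disease axis is the union of diseases seen in either file, filtered
    to diseases linked to at least one drug *and* one microbe (when both
    files are given). Pairs naming drugs/microbes absent from the dataset
    are dropped.
    """
    def _pairs(path):
        sep = _infer_sep(path, format)
        df = pd.read_csv(path, sep=sep, dtype=str, header=0)
        return list(zip(df.iloc[:, 0], df.iloc[:, 1]))

    dd = _pairs(drug_disease_path) if drug_disease_path else []
    md = _pairs(microbe_disease_path) if microbe_disease_path else []
    dd = [(a, b) for a, b in dd if a in set(dataset.drug_ids)]
    md = [(a, b) for a, b in md if a in set(dataset.microbe_ids)]
    drug_dis = {b for _, b in dd}
    mic_dis = {b for _, b in md}
    if dd and md:
        keep = drug_dis & mic_dis
    else:
        keep = drug_dis | mic_dis
    disease_ids = sorted(keep)
    idx = {d: i for i, d in enumerate(disease_ids)}
    D_r = np.zeros((dataset.n_drugs, len(disease_ids)))
    D_m = np.zeros((dataset.n_microbes, len(disease_ids)))
    d_index = {d: i for i, d in enumerate(dataset.drug_ids)}
    m_index = {m: j for j, m in enumerate(dataset.microbe_ids)}
    for a, b in dd:
        if b in idx:
            D_r[d_index[a], idx[b]] = 1.0
    for a, b in md:
        if b in idx:
            D_m[m_index[a], idx[b]] = 1.0
    return AssociationDataset(
        drug_ids=dataset.drug_ids,
        microbe_ids=dataset.microbe_ids,
        A=dataset.A,
        disease_ids=disease_ids,
        drug_disease=D_r,
        microbe_disease=D_m,
        drug_chemical_sim=dataset.drug_chemical_sim,
        microbe_functional_sim=dataset.microbe_functional_sim,
    )


def _infer_sep(path, format: str | None) -> str:
    if format is not None:
        if format not in ("tsv", "csv"):
            raise ValueError(f"format must be 'tsv' or 'csv', got {format!r}")
        return "\t" if format == "tsv" else ","
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a dense matrix with row-id index column and column-id header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def write_matrix_tsv(path, M: np.ndarray, row_ids, col_ids) -> None:
    pd.DataFrame(M, index=row_ids, columns=col_ids).to_csv(path, sep="\t")


def write_score_matrix(
    scores: np.ndarray,
    drug_ids: list[str],
    microbe_ids: list[str],
    path,
    A: np.ndarray | None = None,
) -> None:
    """Write scores as long-format TSV sorted by descending score.

    Columns: drug_id, microbe_id, score, known (0/1; all 0 when ``A`` is not
    given). Ties are broken by (drug_id, microbe_id) so output is stable.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("score matrix contains non-finite entries")
    if scores.shape != (len(drug_ids), len(microbe_ids)):
        raise ValueError("score matrix shape does not match id registries")
    known = A if A is not None else np.zeros_like(scores)
    df = pd.DataFrame(
        {
            "drug_id": np.repeat(drug_ids, len(microbe_ids)),
            "microbe_id": np.tile(microbe_ids, len(drug_ids)),
            "score": scores.ravel(),
            "known": known.ravel().astype(int),
        }
    )
    df = df.sort_values(
        ["score", "drug_id", "microbe_id"], ascending=[False, True, True], kind="mergesort"
    )
    df.to_csv(path, sep="\t", index=False)


def read_score_matrix(path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_score_matrix` output."""
    return pd.read_csv(path, sep="\t", dtype={"drug_id": str, "microbe_id": str})
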