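"""Readers, writers and validated containers for the pipeline's tabular inputs.

All inputs are plain TSV/CSV:

* quantitative matrix — rows are protein identifiers, columns sample
  identifiers, cells log-scale abundances (missing allowed);
* sample design — ``sample_id``, ``group`` (``reference``/``test``) and an
  optional finer ``subtype`` label;
* pair list — two protein-ID columns (optional third ``source`` column);
* exclusion lists — one protein ID per line;
* complex catalog — ``complex_id``, ``name``, ``member_id`` rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("alteredpqr")

#: cell contents mapped to the internal missing state
MISSING_TOKENS = ("", "NA", "NaN", "nan", "NAN", "N/A", "na", "null", "NULL")

GROUP_TOKENS = ("reference", "test")


def pair_id(a: str, b: str) -> str:
    """Canonical identifier of an unordered protein pair (alphabetical)."""
    a, b = sorted((str(a), str(b)))
    return f"{a}::{b}"


@dataclass(frozen=True)
class ExclusionList:
    """Flat set of protein IDs to drop, with the reason they are dropped
    (e.g. a GO term such as ``GO:0005200`` for cytoskeletal proteins)."""

    protein_ids: frozenset
    reason: str

    def __post_init__(self):
        if any(not str(p) for p in self.protein_ids):
            raise ValueError("exclusion list contains an empty identifier")


def _read_table(path, delimiter):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)


def read_quant_matrix(path, delimiter: str = "\t", already_log: bool = True,
                      log_base: float = 2.0) -> pd.DataFrame:
    """Read a protein × sample abundance matrix.

    The first column holds protein IDs, the header row sample IDs. When
    ``already_log`` is false the raw intensities are log-transformed with
    ``log_base`` and non-positive values become missing.

    Returns a float DataFrame (NaN = missing) indexed by protein ID.
    """
    raw = _read_table(path, delimiter)
    if raw.shape[1] < 3:
        raise ValueError(
            f"{path}: need a protein-ID column and at least 2 sample columns, "
            f"got {raw.shape[1]} columns")
    raw = raw.set_index(raw.columns[0])
    raw.index = raw.index.str.strip()
    raw.index.name = "protein_id"
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated protein ID {dup!r}")
    if pd.Index(raw.columns).duplicated().any():
        dup = raw.columns[pd.Index(raw.columns).duplicated()][0]
        raise ValueError(f"{path}: duplicated sample ID {dup!r}")
    if (raw.index == "").any():
        raise ValueError(f"{path}: empty protein identifier")

    cleaned = raw.replace(dict.fromkeys(MISSING_TOKENS, np.nan))
    values = cleaned.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & cleaned.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {cleaned.iat[i, j]!r} at protein "
            f"{values.index[i]!r}, sample {values.columns[j]!r}")
    values = values.astype(float)
    if np.isinf(values.to_numpy()).any():
        raise ValueError(f"{path}: matrix contains non-finite values")

    if not already_log:
        nonpos = (values <= 0)
        n_nonpos = int(nonpos.to_numpy().sum())
        if n_nonpos:
            logger.warning("%s: %d non-positive raw values set to missing",
                           path, n_nonpos)
        values = values.mask(nonpos)
        values = np.log(values) / np.log(log_base)
    validate_quant_matrix(values)
    return values


def validate_quant_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the QuantMatrix invariants (unique IDs, finite-or-missing values)."""
    if matrix.shape[0] < 1 or matrix.shape[1] < 2:
        raise ValueError("matrix needs at least 1 protein and 2 samples")
    if matrix.index.duplicated().any():
        raise ValueError("duplicated protein IDs")
    if pd.Index(matrix.columns).duplicated().any():
        raise ValueError("duplicated sample IDs")
    if np.isinf(matrix.to_numpy(dtype=float)).any():
        raise ValueError("matrix contains non-finite values")
    return matrix


def write_quant_matrix(matrix: pd.DataFrame, path, delimiter: str = "\t") -> None:
    matrix.to_csv(path, sep=delimiter)


def read_design(path, matrix: pd.DataFrame | None = None,
                delimiter: str = "\t") -> pd.DataFrame:
    """Read the sample design (``sample_id``, ``group``, optional ``subtype``).

    ``group`` must be ``reference`` or ``test``. When a matrix is given,
    design rows naming samples absent from the matrix are dropped with a
    warning; at least 2 reference and 1 test sample must remain.
    """
    df = _read_table(path, delimiter)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: design needs sample_id and group columns")
    design = pd.DataFrame({
        "group": df.iloc[:, 1].str.strip().to_numpy(),
        "subtype": (df.iloc[:, 2] if df.shape[1] >= 3
                    else df.iloc[:, 1]).str.strip().to_numpy(),
    }, index=pd.Index(df.iloc[:, 0].str.strip().to_numpy(),
                      name="sample_id"))
    design.loc[design["subtype"] == "", "subtype"] = design["group"]
    if design.index.duplicated().any():
        dup = design.index[design.index.duplicated()][0]
        raise ValueError(f"{path}: sample {dup!r} listed more than once")
    unknown = sorted(set(design["group"]) - set(GROUP_TOKENS))
    if unknown:
        raise ValueError(
            f"{path}: unknown group token(s) {unknown}; allowed tokens are "
            f"{list(GROUP_TOKENS)}")
    if matrix is not None:
        extra = design.index.difference(matrix.columns)
        if len(extra):
            warnings.warn(
                f"{len(extra)} design sample(s) not in the matrix ignored: "
                f"{sorted(extra)[:5]}", stacklevel=2)
            design = design.drop(index=extra)
        undesigned = matrix.columns.difference(design.index)
        if len(undesigned):
            logger.info("%d matrix sample(s) not in the design are ignored",
                        len(undesigned))
    return validate_design(design)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    n_ref = int((design["group"] == "reference").sum())
    n_test = int((design["group"] == "test").sum())
    if n_ref < 2:
        raise ValueError(f"need at least 2 reference samples, got {n_ref}")
    if n_test < 1:
        raise ValueError(f"need at least 1 test sample, got {n_test}")
    return design


def design_groups(design: pd.DataFrame,
                  matrix: pd.DataFrame | None = None) -> tuple[list, list]:
    """Reference and test sample IDs, ordered like the matrix columns."""
    ref = design.index[design["group"] == "reference"]
    test = design.index[design["group"] == "test"]
    if matrix is not None:
        ref = [s for s in matrix.columns if s in set(ref)]
        test = [s for s in matrix.columns if s in set(test)]
    return list(ref), list(test)


def make_pairs(pairs, matrix: pd.DataFrame | None = None,
               sources=None) -> pd.DataFrame:
    """Build a canonical pair table from (a, b) tuples.

    Pairs are unordered: each is stored alphabetically and deduplicated.
    Self-pairs are dropped with a warning. Pairs with a protein absent from
    ``matrix`` are retained but flagged ``measured=False``.
    """
    rows = []
    n_self = 0
    for k, (a, b) in enumerate(pairs):
        a, b = str(a).strip(), str(b).strip()
        if not a or not b:
            raise ValueError(f"empty protein ID in pair row {k}")
        if a == b:
            n_self += 1
            continue
        a, b = sorted((a, b))
        src = "" if sources is None else str(sources[k])
        rows.append((pair_id(a, b), a, b, src))
    if n_self:
        warnings.warn(f"{n_self} self-pair(s) dropped", stacklevel=2)
    table = pd.DataFrame(rows, columns=["pair", "protein_a", "protein_b",
                                        "source"]).drop_duplicates("pair")
    table = table.set_index("pair").sort_index()
    if matrix is not None:
        measured = set(matrix.index)
        table["measured"] = (table["protein_a"].isin(measured)
                             & table["protein_b"].isin(measured))
    else:
        table["measured"] = True
    return table


def read_pairs(path, matrix: pd.DataFrame | None = None,
               delimiter: str = "\t") -> pd.DataFrame:
    """Read a stable-interaction pair list (two ID columns, optional source)."""
    df = _read_table(path, delimiter)
    if df.empty:
        raise ValueError(f"{path}: pair list is empty")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: pair list needs two protein-ID columns")
    sources = df.iloc[:, 2].tolist() if df.shape[1] >= 3 else None
    pairs = make_pairs(list(zip(df.iloc[:, 0], df.iloc[:, 1])),
                       matrix=matrix, sources=sources)
    if pairs.empty:
        raise ValueError(f"{path}: no usable pairs")
    n_unmeasured = int((~pairs["measured"]).sum())
    if n_unmeasured:
        logger.info("%d pair(s) contain unmeasured proteins", n_unmeasured)
    return pairs


def read_exclusion_list(path, reason: str | None = None) -> ExclusionList:
    """Read a flat protein-ID exclusion list (one ID per line, ``#`` comments)."""
    path = Path(path)
    ids = []
    for line in path.read_text().splitlines():
        token = line.split("\t")[0].strip()
        if token and not token.startswith("#"):
            ids.append(token)
    return ExclusionList(frozenset(ids), reason or path.stem)


def read_complex_catalog(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a complex catalog: one ``complex_id, name, member_id`` row per
    subunit (two-column files reuse the ID as the name). Complexes with a
    single listed member are dropped with a warning."""
    df = _read_table(path, delimiter)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: catalog needs complex_id and member columns")
    if df.shape[1] == 2:
        cat = pd.DataFrame({"complex_id": df.iloc[:, 0], "name": df.iloc[:, 0],
                            "member_id": df.iloc[:, 1]})
    else:
        cat = pd.DataFrame({"complex_id": df.iloc[:, 0], "name": df.iloc[:, 1],
                            "member_id": df.iloc[:, 2]})
    cat = cat.apply(lambda c: c.str.strip()).drop_duplicates()
    sizes = cat.groupby("complex_id")["member_id"].nunique()
    small = sizes.index[sizes < 2]
    if len(small):
        warnings.warn(f"{len(small)} complex(es) with <2 members dropped",
                      stacklevel=2)
        cat = cat[~cat["complex_id"].isin(small)]
    return cat.reset_index(drop=True)


def catalog_members(catalog: pd.DataFrame) -> dict:
    """Map complex_id -> (name, sorted member list)."""
    out = {}
    for cid, grp in catalog.groupby("complex_id"):
        out[cid] = (grp["name"].iloc[0], sorted(grp["member_id"].unique()))
    return out


def write_table(df: pd.DataFrame, path, delimiter: str = "\t",
                index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=delimiter, index=index)
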