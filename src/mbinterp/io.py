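"""Reading and writing feature tables and sample-time metadata.

Feature tables are delimited text (TSV/CSV, auto-sniffed), either taxa x
samples or samples x taxa (orientation auto-detected against the metadata's
sample ids).  Metadata is a two-column table mapping ``sample_id`` to ``day``.
BIOM v2.1 (HDF5) tables are supported through a minimal reader.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .profiles import LongitudinalProfile

__all__ = ["read_profile", "read_time_metadata", "write_profile", "read_biom_table"]


def read_time_metadata(source) -> dict[str, float]:
    """Load a sample -> day mapping from a path, DataFrame, or mapping."""
    if isinstance(source, Mapping):
        return {str(k): float(v) for k, v in source.items()}
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError("time metadata needs two columns: sample_id, day")
    return {str(s): float(d) for s, d in zip(df.iloc[:, 0], df.iloc[:, 1])}


def _load_table(table_source) -> pd.DataFrame:
    if isinstance(table_source, pd.DataFrame):
        return table_source.copy()
    path = os.fspath(table_source)
    if path.endswith(".biom"):
        return read_biom_table(path)
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_biom_table(path) -> pd.DataFrame:
    """Read a BIOM v2.1 (HDF5) table into a taxa x samples DataFrame."""
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as fh:
        obs_ids = [x.decode() if isinstance(x, bytes) else str(x)
                   for x in fh["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x)
                      for x in fh["sample/ids"][:]]
        data = fh["observation/matrix/data"][:]
        indices = fh["observation/matrix/indices"][:]
        indptr = fh["observation/matrix/indptr"][:]
    mat = sparse.csr_matrix(
        (data, indices, indptr), shape=(len(obs_ids), len(sample_ids))
    )
    return pd.DataFrame(mat.toarray(), index=obs_ids, columns=sample_ids)


def read_profile(
    table_source,
    time_metadata,
    individual_id: str,
    orientation: str = "auto",
    dataset: str = "default",
) -> LongitudinalProfile:
    """Build a :class:`LongitudinalProfile` from a feature table and times.

    Parameters
    ----------
    table_source
        Path to a delimited table or BIOM file, or a DataFrame.  Rows may be
        taxa and columns samples, or vice versa (``orientation='auto'``
        resolves against the metadata sample ids).
    time_metadata
        Path / DataFrame / mapping giving each sample id its day.
    individual_id
        Label attached to the resulting profile.
    orientation
        ``'taxa_by_samples'``, ``'samples_by_taxa'``, or ``'auto'``.

    Raw values may be counts or proportions; every sample is renormalized to
    relative abundance.  Samples are sorted by time.  Missing time stamps,
    duplicate days, and all-zero samples are input errors.
    """
    table = _load_table(table_source)
    times = read_time_metadata(time_metadata)

    cols = [str(c) for c in table.columns]
    rows = [str(r) for r in table.index]
    if orientation == "auto":
        col_hits = sum(c in times for c in cols) / max(len(cols), 1)
        row_hits = sum(r in times for r in rows) / max(len(rows), 1)
        if col_hits == 0 and row_hits == 0:
            raise ValueError(
                "cannot determine table orientation: no sample id from the "
                "metadata matches the table's rows or columns"
            )
        orientation = ("taxa_by_samples" if col_hits >= row_hits
                       else "samples_by_taxa")
    if orientation == "taxa_by_samples":
        table = table.T
    elif orientation != "samples_by_taxa":
        raise ValueError(f"unknown orientation {orientation!r}")

    sample_ids = [str(s) for s in table.index]
    missing = [s for s in sample_ids if s not in times]
    if missing:
        raise ValueError(f"samples without a time stamp: {missing[:5]}")
    day = np.array([times[s] for s in sample_ids], dtype=float)
    if np.unique(day).size != day.size:
        raise ValueError("duplicate sample times for one individual")

    values = table.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("abundances must be non-negative")
    row_sums = values.sum(axis=1)
    if np.any(row_sums <= 0):
        bad = [sample_ids[i] for i in np.flatnonzero(row_sums <= 0)]
        raise ValueError(f"all-zero samples: {bad[:5]}")
    values = values / row_sums[:, None]

    order = np.argsort(day)
    day = day[order] - day[order[0]]
    values = values[order]
    return LongitudinalProfile(
        individual_id=individual_id,
        times=day,
        taxa=tuple(str(t) for t in table.columns),
        abundances=values,
        dataset=dataset,
    )


def write_profile(profile: LongitudinalProfile, table_path, meta_path=None) -> None:
    """Write a profile as a taxa x samples table (full-precision decimals).

    Sample ids are ``<individual_id>_t<index>``; if ``meta_path`` is given, a
    matching two-column metadata table is written alongside.
    """
    sample_ids = [f"{profile.individual_id}_t{i}" for i in range(profile.n_samples)]
    df = pd.DataFrame(
        profile.abundances.T, index=list(profile.taxa), columns=sample_ids
    )
    sep = "," if str(table_path).endswith(".csv") else "\t"
    df.to_csv(table_path, sep=sep, float_format="%.17g", index_label="taxon")
    if meta_path is not None:
        meta = pd.DataFrame({"sample_id": sample_ids, "day": profile.times})
        meta.to_csv(meta_path, sep=sep, index=False, float_format="%.17g")
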