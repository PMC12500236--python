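"""Protein quantification tables: container, readers, writers, annotation.

The central in-memory object is :class:`ProteinQuantTable`, a thin wrapper
around three aligned pandas frames:

``intensities``
    proteins x samples matrix of non-negative label-free quantification (LFQ)
    intensities.  A value of 0 means *not observed* (the MetaMorpheus export
    convention); zeros are converted to missing only at the log2 stage.
``samples``
    per-sample metadata (model, treatment, fraction, replicate).
``annotations``
    per-protein metadata (gene symbol, species, matrisome division/category).

Files are plain text: the intensity matrix as TSV (one protein per row, one
column per sample), metadata and annotations as CSV.  Lines starting with
``#`` are provenance comments and are skipped on read.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REQUIRED_METADATA = ("model", "treatment", "fraction", "replicate")

SPECIES_HUMAN = "human"
SPECIES_RAT = "rat"
SPECIES_UNKNOWN = "unknown"

DIVISION_CORE = "core matrisome"
DIVISION_ASSOCIATED = "matrisome-associated"
DIVISION_NONE = "non-matrisome"

CATEGORY_NONE = "none"

#: matrisome category -> division (Naba-style inventory layout)
CATEGORY_DIVISION: Mapping[str, str] = {
    "collagens": DIVISION_CORE,
    "ecm_glycoproteins": DIVISION_CORE,
    "proteoglycans": DIVISION_CORE,
    "ecm_regulators": DIVISION_ASSOCIATED,
    "ecm_affiliated": DIVISION_ASSOCIATED,
    "secreted_factors": DIVISION_ASSOCIATED,
    CATEGORY_NONE: DIVISION_NONE,
}

MATRISOME_CATEGORIES = tuple(c for c in CATEGORY_DIVISION if c != CATEGORY_NONE)


class TableValidationError(ValueError):
    """Raised when a quantification table violates its invariants."""


def infer_species(protein_id: str) -> str:
    """Species from the UniProt-style accession suffix (``_HUMAN``/``_RAT``)."""
    if protein_id.endswith("_HUMAN"):
        return SPECIES_HUMAN
    if protein_id.endswith("_RAT"):
        return SPECIES_RAT
    return SPECIES_UNKNOWN


@dataclass
class ProteinQuantTable:
    """Proteins x samples intensity matrix with aligned metadata.

    Invariants (checked on construction): intensities are finite and >= 0
    with unique protein ids; every intensity column has a complete metadata
    row; annotations cover every protein.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        idx = self.intensities.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate protein_id values: {dupes[:5]}")
        values = self.intensities.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise TableValidationError(
                "intensities contain NaN/inf; encode non-detection as 0"
            )
        if values.size and (values < 0).any():
            bad = self.intensities.columns[(values < 0).any(axis=0)].tolist()
            raise TableValidationError(f"negative intensities in samples: {bad}")
        missing_meta = [c for c in self.intensities.columns if c not in self.samples.index]
        if missing_meta:
            raise TableValidationError(
                f"samples without metadata: {missing_meta}"
            )
        for col in REQUIRED_METADATA:
            if col not in self.samples.columns:
                raise TableValidationError(f"sample metadata is missing column {col!r}")
            if self.samples.loc[list(self.intensities.columns), col].isna().any():
                raise TableValidationError(f"sample metadata column {col!r} has missing values")
        missing_ann = idx.difference(self.annotations.index)
        if len(missing_ann):
            raise TableValidationError(
                f"proteins without annotation rows: {missing_ann[:5].tolist()}"
            )

    # -- convenience -----------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def copy(self) -> "ProteinQuantTable":
        return ProteinQuantTable(
            self.intensities.copy(), self.samples.copy(), self.annotations.copy()
        )

    def sample_totals(self) -> pd.Series:
        """Per-sample total intensity (sum over proteins)."""
        return self.intensities.sum(axis=0)

    def nonzero_counts(self) -> pd.Series:
        """Per-sample number of detected (nonzero) protein groups."""
        return (self.intensities > 0).sum(axis=0)

    def metadata_for(self, sample_id: str) -> pd.Series:
        return self.samples.loc[sample_id]

    def matching_samples(self, **criteria) -> list[str]:
        """Sample ids whose metadata matches every ``field=value`` criterion.

        A criterion value may be a scalar or an iterable of admissible values.
        """
        mask = pd.Series(True, index=self.samples.index)
        for key, value in criteria.items():
            if key not in self.samples.columns:
                raise KeyError(f"unknown sample metadata field {key!r}")
            if isinstance(value, (list, tuple, set, frozenset)):
                mask &= self.samples[key].isin(list(value))
            else:
                mask &= self.samples[key] == value
        selected = [s for s in self.intensities.columns if mask.loc[s]]
        return selected

    def select_samples(self, sample_ids: Sequence[str] | None = None, **criteria) -> "ProteinQuantTable":
        if sample_ids is None:
            sample_ids = self.matching_samples(**criteria)
        elif criteria:
            raise ValueError("pass either explicit sample_ids or metadata criteria, not both")
        return ProteinQuantTable(
            self.intensities.loc[:, list(sample_ids)],
            self.samples.loc[list(sample_ids)].copy(),
            self.annotations.copy(),
        )

    def select_proteins(self, protein_ids: Iterable[str] | pd.Series) -> "ProteinQuantTable":
        if isinstance(protein_ids, pd.Series) and protein_ids.dtype == bool:
            protein_ids = protein_ids[protein_ids].index
        protein_ids = list(protein_ids)
        return ProteinQuantTable(
            self.intensities.loc[protein_ids],
            self.samples.copy(),
            self.annotations.loc[protein_ids].copy(),
        )

    def with_intensities(self, intensities: pd.DataFrame) -> "ProteinQuantTable":
        return ProteinQuantTable(
            intensities,
            self.samples.loc[list(intensities.columns)].copy(),
            self.annotations.loc[intensities.index].copy(),
        )


# ---------------------------------------------------------------------------
# reading


def _read_text_frame(path: str | Path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata CSV (columns: sample + model/treatment/fraction/replicate)."""
    meta = _read_text_frame(path, ",")
    if "sample" not in meta.columns:
        raise TableValidationError("metadata file must have a 'sample' column")
    missing = [c for c in REQUIRED_METADATA if c not in meta.columns]
    if missing:
        raise TableValidationError(f"metadata file is missing columns: {missing}")
    return meta.set_index("sample")


def read_quant_table(
    path: str | Path,
    metadata_path: str | Path,
    annotation: pd.DataFrame | str | Path | None = None,
) -> ProteinQuantTable:
    """Read a wide TSV quantification table plus its sample metadata.

    The TSV must have a ``protein_id`` column; ``gene`` and ``species``
    columns are optional (species falls back to the accession suffix
    convention ``_HUMAN``/``_RAT``).  Every remaining column must be mapped
    by the metadata file and vice versa.
    """
    raw = _read_text_frame(path, "\t")
    if "protein_id" not in raw.columns:
        raise TableValidationError("quant table must have a 'protein_id' column")
    samples = read_sample_metadata(metadata_path)

    annotation_cols = [c for c in ("protein_id", "gene", "species", "division", "category") if c in raw.columns]
    intensity_cols = [c for c in raw.columns if c not in annotation_cols]
    unmapped = [c for c in intensity_cols if c not in samples.index]
    if unmapped:
        raise TableValidationError(
            f"intensity columns without metadata: {unmapped}"
        )
    absent = [s for s in samples.index if s not in intensity_cols]
    if absent:
        raise TableValidationError(f"metadata samples missing from quant table: {absent}")

    intens = raw.set_index("protein_id")[intensity_cols].astype(float)
    ann = pd.DataFrame(index=intens.index)
    ann["gene"] = raw.set_index("protein_id").get("gene", pd.Series("", index=intens.index))
    if "species" in raw.columns:
        ann["species"] = raw.set_index("protein_id")["species"]
    else:
        ann["species"] = [infer_species(p) for p in intens.index]
    indexed = raw.set_index("protein_id")
    ann["division"] = indexed["division"] if "division" in raw.columns else DIVISION_NONE
    ann["category"] = indexed["category"] if "category" in raw.columns else CATEGORY_NONE
    table = ProteinQuantTable(intens, samples, ann)
    if annotation is not None:
        table = attach_annotations(table, annotation)
    return table


# ---------------------------------------------------------------------------
# matrisome annotation


def load_matrisome_annotation(path: str | Path) -> pd.DataFrame:
    """Load a matrisome annotation CSV (columns: accession, division, category)."""
    ann = _read_text_frame(path, ",")
    required = {"accession", "division", "category"}
    missing = required.difference(ann.columns)
    if missing:
        raise TableValidationError(f"annotation file is missing columns: {sorted(missing)}")
    bad = [
        (row.accession, row.category, row.division)
        for row in ann.itertuples()
        if CATEGORY_DIVISION.get(row.category) not in (None, row.division)
    ]
    if bad:
        raise TableValidationError(
            f"category/division mismatch for accessions: {[b[0] for b in bad[:5]]}"
        )
    return ann.set_index("accession")


def mini_matrisome() -> pd.DataFrame:
    """The packaged miniature matrisome annotation (~60 well-known ECM accessions)."""
    ref = importlib.resources.files("newsecm") / "data" / "matrisome_mini.csv"
    with importlib.resources.as_file(ref) as path:
        return load_matrisome_annotation(path)


def attach_annotations(
    table: ProteinQuantTable, annotation: pd.DataFrame | str | Path
) -> ProteinQuantTable:
    """Attach matrisome division/category to every protein.

    Accessions absent from the annotation default to non-matrisome / none.
    """
    if not isinstance(annotation, pd.DataFrame):
        annotation = load_matrisome_annotation(annotation)
    ann = table.annotations.copy()
    matched = ann.index.intersection(annotation.index)
    ann["division"] = DIVISION_NONE
    ann["category"] = CATEGORY_NONE
    ann.loc[matched, "division"] = annotation.loc[matched, "division"]
    ann.loc[matched, "category"] = annotation.loc[matched, "category"]
    return ProteinQuantTable(table.intensities.copy(), table.samples.copy(), ann)


# ---------------------------------------------------------------------------
# writing


def write_frame(
    df: pd.DataFrame,
    path: str | Path,
    header: Sequence[str] = (),
    overwrite: bool = False,
    sep: str = ",",
    index: bool = True,
) -> Path:
    """Write a frame as delimited text with optional ``#`` provenance header."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=index)
    return path


def write_quant_table(
    table: ProteinQuantTable,
    out_dir: str | Path,
    prefix: str = "quant",
    header: Sequence[str] = (),
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write intensities (TSV) + metadata and annotations (CSV).

    Returns the mapping of logical name -> written path.  Column order is the
    table's own, so repeated writes of the same table are byte-identical.
    """
    out_dir = Path(out_dir)
    wide = table.annotations.join(table.intensities)
    wide.index.name = "protein_id"
    paths = {
        "intensities": write_frame(
            wide, out_dir / f"{prefix}_intensities.tsv", header, overwrite, sep="\t"
        ),
        "samples": write_frame(
            table.samples.rename_axis("sample"),
            out_dir / f"{prefix}_samples.csv",
            header,
            overwrite,
        ),
    }
    return paths


def read_written_quant_table(out_dir: str | Path, prefix: str = "quant") -> ProteinQuantTable:
    """Round-trip reader for :func:`write_quant_table` output."""
    out_dir = Path(out_dir)
    return read_quant_table(
        out_dir / f"{prefix}_intensities.tsv", out_dir / f"{prefix}_samples.csv"
    )
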