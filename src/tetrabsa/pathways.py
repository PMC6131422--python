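"""KEGG/EC annotation joining and curated caffeine-pathway narrowing.

The gene -> pathway annotation table follows a Blast2GO-export-like TSV
contract (cds_id, pathway, ec_number, enzyme_label). Candidate narrowing
intersects annotated trait-associated variants with a curated
substrate-pathway-EC table of the caffeine biosynthesis network; the
packaged table covers seven pathways, ten enzymes and eight substrates
totalling 65 sequences.
"""

from __future__ import annotations

import re
import warnings
from importlib import resources

import pandas as pd

from .errors import ConfigurationError

_EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")

CURATED_COLUMNS = [
    "substrate",
    "pathway",
    "ec_number",
    "enzyme_label",
    "metabolism_type",
    "n_sequences",
    "duplication_note",
]


def _norm(value: str) -> str:
    return str(value).strip().casefold()


def normalize_ec(value: str) -> str:
    """Trim, casefold and strip any 'EC:' prefix from an EC code."""
    text = _norm(value)
    if text.startswith("ec:"):
        text = text[3:]
    return text.strip()


def load_curated(path=None) -> pd.DataFrame:
    """Load the curated substrate-pathway-EC table (packaged fixture by default)."""
    if path is None:
        source = resources.files("tetrabsa.data") / "curated_caffeine_pathways.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype={"n_sequences": int})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"n_sequences": int})
    missing = [c for c in CURATED_COLUMNS if c not in df.columns and c != "duplication_note"]
    if missing:
        raise ConfigurationError(f"curated table missing columns: {missing}")
    if "duplication_note" not in df.columns:
        df["duplication_note"] = ""
    df["duplication_note"] = df["duplication_note"].fillna("")
    if (df["n_sequences"] < 1).any():
        raise ConfigurationError("n_sequences must be >= 1 in every curated row")
    bad_type = ~df["metabolism_type"].isin(["A", "C"])
    if bad_type.any():
        raise ConfigurationError("metabolism_type must be 'A' (anabolism) or 'C' (catabolism)")
    return df


def load_annotation_table(path) -> pd.DataFrame:
    """Read a gene -> pathway/EC TSV, warning on malformed EC codes (kept raw)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cds_id", "pathway", "ec_number"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"annotation table missing columns: {sorted(missing)}")
    if "enzyme_label" not in df.columns:
        df["enzyme_label"] = ""
    _warn_malformed_ec(df["ec_number"])
    return df


def _warn_malformed_ec(series: pd.Series) -> None:
    for value in series.dropna().unique():
        if not _EC_PATTERN.match(normalize_ec(value)):
            warnings.warn(f"malformed EC code kept as-is: {value!r}", stacklevel=3)


def tavs_to_frame(tavs) -> pd.DataFrame:
    """Flatten Tav records into the table the pathway stages operate on."""
    rows = []
    for t in tavs:
        bc = t.contrast
        rows.append(
            {
                "contig": bc.contig,
                "position": bc.position,
                "ref_allele": bc.ref_allele,
                "allele": t.allele,
                "gene_id": t.gene_id,
                "cds_id": t.cds_id,
                "p_value": bc.p_value,
                "chi2_statistic": bc.chi2_statistic,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["contig", "position", "ref_allele", "allele", "gene_id", "cds_id", "p_value", "chi2_statistic"],
    )


def join_annotations(tavs, annotation_table: pd.DataFrame) -> pd.DataFrame:
    """Left-join TAVs with the pathway/EC table on cds_id.

    TAVs on unannotated CDS are retained with empty pathway fields; a CDS
    with several (pathway, EC) terms contributes one output row per term.
    """
    tav_frame = tavs if isinstance(tavs, pd.DataFrame) else tavs_to_frame(tavs)
    annot = annotation_table.copy()
    _warn_malformed_ec(annot["ec_number"])
    joined = tav_frame.merge(
        annot[["cds_id", "pathway", "ec_number", "enzyme_label"]], on="cds_id", how="left"
    )
    for col in ("pathway", "ec_number", "enzyme_label"):
        joined[col] = joined[col].fillna("")
    return joined


def filter_curated(joined_tavs: pd.DataFrame, curated_rows: pd.DataFrame) -> pd.DataFrame:
    """Keep joined rows whose (pathway, EC) pair is in the curated set.

    Matching is case-insensitive, whitespace-trimmed and 'EC:'-prefix
    agnostic. Candidates are deduplicated per (cds_id, position, allele).
    """
    if curated_rows is None or len(curated_rows) == 0:
        raise ConfigurationError("curated pathway set is empty")
    curated_keys = {
        (_norm(p), normalize_ec(e))
        for p, e in zip(curated_rows["pathway"], curated_rows["ec_number"])
    }
    keys = [
        (_norm(p), normalize_ec(e))
        for p, e in zip(joined_tavs["pathway"], joined_tavs["ec_number"])
    ]
    mask = [k in curated_keys for k in keys]
    candidates = joined_tavs.loc[mask]
    return candidates.drop_duplicates(subset=["cds_id", "position", "allele"]).reset_index(drop=True)


def summarize_curated(curated_rows: pd.DataFrame) -> dict:
    """Summary arithmetic of a curated table.

    Unique pathway / enzyme (EC) / substrate counts after exact-string
    normalization, the total sequence count, and the number of distinct
    substrates feeding each pathway. Row order never matters.
    """
    if len(curated_rows) == 0:
        return {
            "unique_pathways": 0,
            "unique_enzymes": 0,
            "unique_substrates": 0,
            "total_sequences": 0,
            "per_pathway_substrates": {},
        }
    pathways = curated_rows["pathway"].map(_norm)
    enzymes = curated_rows["ec_number"].map(normalize_ec)
    substrates = curated_rows["substrate"].map(_norm)
    per_pathway = (
        pd.DataFrame({"pathway": pathways, "substrate": substrates})
        .groupby("pathway")["substrate"]
        .nunique()
        .to_dict()
    )
    return {
        "unique_pathways": int(pathways.nunique()),
        "unique_enzymes": int(enzymes.nunique()),
        "unique_substrates": int(substrates.nunique()),
        "total_sequences": int(curated_rows["n_sequences"].sum()),
        "per_pathway_substrates": per_pathway,
    }
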