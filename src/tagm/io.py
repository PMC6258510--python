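"""Delimited-text I/O for quantitation matrices, marker tables and results.

Quantitation files are TSV/CSV with a header row of fraction names and the
protein id in the first column. Marker files are two-column (protein id,
class), header optional. Delimiters are auto-detected; files are UTF-8
with dot decimal separators.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, Hyperparameters, MarkerAnnotation

__all__ = [
    "read_quantitation",
    "write_quantitation",
    "read_markers",
    "write_markers",
    "write_results",
    "write_manifest",
]

_FLOAT_FMT = "%.6g"  # 6 significant digits: diff-friendly, within declared tolerances


def _detect_sep(path: Path) -> str:
    first = path.read_text(encoding="utf-8").splitlines()[0]
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_quantitation(path) -> ExpressionMatrix:
    """Read a proteins x fractions table; raises on duplicates, ragged rows
    or non-numeric cells, naming the offending line."""
    path = Path(path)
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, encoding="utf-8")
    except pd.errors.ParserError as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein id(s) in {path}: {dupes[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for line_no, (_, row) in enumerate(df.iterrows(), start=2):
            try:
                row.astype(float)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell at line {line_no} of {path}"
                ) from None
        raise
    return ExpressionMatrix(
        values=values,
        protein_ids=tuple(str(i) for i in df.index),
        fraction_ids=tuple(str(c) for c in df.columns),
    )


def write_quantitation(matrix: ExpressionMatrix, path, sep: str = "\t") -> None:
    df = matrix.to_dataframe()
    df.index.name = "protein_id"
    df.to_csv(path, sep=sep, float_format="%.10g", encoding="utf-8")


def read_markers(path, matrix: ExpressionMatrix) -> MarkerAnnotation:
    """Read a two-column marker table, auto-detecting whether a header row
    is present; the class catalogue is built in first-appearance order."""
    path = Path(path)
    sep = _detect_sep(path)
    rows: list[tuple[str, str]] = []
    lines = path.read_text(encoding="utf-8").splitlines()
    known = set(matrix.protein_ids)
    for line_no, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) != 2:
            raise ValueError(f"expected 2 columns at line {line_no} of {path}, got {len(parts)}")
        pid, cls = parts
        if line_no == 1 and pid not in known:
            continue  # header row
        if not cls:
            raise ValueError(f"empty class for protein {pid!r} at line {line_no} of {path}")
        rows.append((pid, cls))
    unknown = [pid for pid, _ in rows if pid not in known]
    if unknown:
        raise ValueError(f"marker protein(s) absent from quantitation: {unknown[:5]}")
    classes: list[str] = []
    labels: dict[str, str] = {}
    for pid, cls in rows:
        if cls not in classes:
            classes.append(cls)
        labels[pid] = cls
    annotation = MarkerAnnotation(labels=labels, classes=tuple(classes))
    annotation.validate_against(matrix)
    return annotation


def write_markers(markers: MarkerAnnotation, path, sep: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"protein_id{sep}markers\n")
        for pid, cls in markers.labels.items():
            fh.write(f"{pid}{sep}{cls}\n")


def write_results(result, out_dir, threshold: float = 0.95, manifest: dict | None = None):
    """Write a result table (and manifest) for a MAP fit or an MCMC summary.

    Column order is deterministic: protein_id, per-class probabilities in
    catalogue order, outlier probability, then for MCMC summaries the
    Shannon entropy and per-class interval bounds, then the classification
    at the given threshold.
    """
    from .map_em import MAPResult
    from .mcmc import PosteriorSummary, classify

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(result, MAPResult):
        classes = result.markers.classes
        df = pd.DataFrame(result.localisation, columns=list(classes))
        df.insert(0, "protein_id", list(result.protein_ids))
        df["outlier_prob"] = result.outlier_prob
        joint = np.column_stack([result.localisation, result.outlier_prob])
        labels = []
        for i, pid in enumerate(result.protein_ids):
            if pid in result.markers.labels:
                labels.append(result.markers.labels[pid])
                continue
            k = int(np.argmax(result.localisation[i]))
            top = result.localisation[i, k]
            if result.outlier_prob[i] > threshold and result.outlier_prob[i] >= top:
                labels.append("outlier")
            elif top > threshold:
                labels.append(classes[k])
            else:
                labels.append("unassigned")
        df["classification"] = labels
        path = out_dir / "tagm_map_results.tsv"
    elif isinstance(result, PosteriorSummary):
        classes = result.classes
        df = pd.DataFrame(result.mean_localisation, columns=list(classes))
        df.insert(0, "protein_id", list(result.protein_ids))
        df["outlier_prob"] = result.outlier_prob
        df["shannon"] = result.shannon
        for k, c in enumerate(classes):
            df[f"lower95_{c}"] = result.lower95[:, k]
            df[f"upper95_{c}"] = result.upper95[:, k]
        df["classification"] = classify(result, threshold=threshold)
        path = out_dir / "tagm_mcmc_results.tsv"
    else:
        raise TypeError(f"cannot write results of type {type(result).__name__}")
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, encoding="utf-8")
    if manifest is not None:
        write_manifest(manifest, out_dir / "run_manifest.txt")
    return path


def write_manifest(entries: dict, path) -> None:
    """Flat key = value manifest, one entry per line, reconstructible."""
    import tagm

    lines = [f"tagm_version = {tagm.__version__}",
             f"python_version = {sys.version.split()[0]}",
             f"numpy_version = {np.__version__}"]
    for key, val in entries.items():
        if isinstance(val, np.ndarray):
            val = np.array2string(val, max_line_width=10**9, precision=8)
        lines.append(f"{key} = {val}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def manifest_from_hyper(hyper: Hyperparameters) -> dict:
    """Every resolved hyperparameter, so a run is reconstructible from its
    manifest alone."""
    return {
        "hyper.beta": hyper.beta,
        "hyper.mu0": hyper.mu0,
        "hyper.lambda0": hyper.lambda0,
        "hyper.nu0": hyper.nu0,
        "hyper.S0": hyper.S0,
        "hyper.u": hyper.u,
        "hyper.v": hyper.v,
        "hyper.kappa": hyper.kappa,
        "hyper.M": hyper.M,
        "hyper.V": hyper.V,
    }


def export_pca_coordinates(matrix: ExpressionMatrix, path, extra: pd.DataFrame | None = None,
                           n_components: int = 4) -> None:
    """Optional convenience export: first principal components of the
    quantitation matrix with any per-protein annotation columns, for
    external visualisation."""
    from sklearn.decomposition import PCA

    n_components = min(n_components, matrix.n_fractions, matrix.n_proteins)
    coords = PCA(n_components=n_components).fit_transform(matrix.values)
    df = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(n_components)])
    df.insert(0, "protein_id", list(matrix.protein_ids))
    if extra is not None:
        df = df.merge(extra, on="protein_id", how="left")
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, encoding="utf-8")
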