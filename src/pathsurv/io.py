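"""Readers and writers for the plain-text exchange formats.

Expression: TSV with samples as rows, a header row of feature ids and the
first column holding sample ids. Pathways: standard GMT. Clinical/survival:
TSV keyed by ``sample_id``. All readers tolerate CRLF and LF line endings
(pandas and the GMT parser strip both).
"""

from __future__ import annotations

import pandas as pd

from .containers import ClinicalTable, OmicsMatrix, PathwayCollection, SurvivalTable

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_survival",
    "write_survival",
    "read_clinical",
    "write_clinical",
]


def read_expression(path, omics_kind: str = "gene") -> OmicsMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.isna().any().any():
        raise ValueError(f"missing values in expression table {path}")
    return OmicsMatrix.from_frame(frame, omics_kind=omics_kind)


def write_expression(matrix: OmicsMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path) -> PathwayCollection:
    pathways, names = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            pid, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if pid in pathways:
                raise ValueError(f"duplicate pathway id {pid!r}")
            pathways[pid] = set(genes)
            names[pid] = desc
    return PathwayCollection(pathways=pathways, names=names)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for pid, genes in collection.pathways.items():
            desc = collection.names.get(pid, pid)
            fh.write("\t".join([pid, desc] + sorted(genes)) + "\n")


def read_survival(path) -> SurvivalTable:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "time", "event"):
        if col not in frame.columns:
            raise ValueError(f"survival table must have a {col!r} column")
    if frame[["time", "event"]].isna().any().any():
        raise ValueError("missing values are forbidden in survival columns")
    return SurvivalTable(
        sample_ids=frame["sample_id"].tolist(),
        time=frame["time"].to_numpy(),
        event=frame["event"].to_numpy(),
    )


def write_survival(surv: SurvivalTable, path) -> None:
    pd.DataFrame(
        {"sample_id": surv.sample_ids, "time": surv.time, "event": surv.event}
    ).to_csv(path, sep="\t", index=False)


def read_clinical(path) -> ClinicalTable:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    if frame.isna().any().any():
        raise ValueError("missing values in clinical table")
    return ClinicalTable(
        sample_ids=frame.index.tolist(),
        values=frame.to_numpy(dtype=float),
        columns=list(frame.columns),
    )


def write_clinical(clin: ClinicalTable, path) -> None:
    frame = pd.DataFrame(clin.values, index=clin.sample_ids, columns=clin.columns)
    frame.to_csv(path, sep="\t", index_label="sample_id")
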