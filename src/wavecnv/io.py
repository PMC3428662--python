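"""Readers and writers for the pipeline's plain-text formats.

Conventions:

* probe annotation TSV — 1-based locus positions, header required;
* all interval outputs (calls, BedGraph) — 0-based half-open, BED-style;
* raw CN tracks — BedGraph (chrom, start, end, value; single-position
  intervals) and a TSV carrying the probeset_id;
* energy model and HMM parameters — JSON (see their classes).
"""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd

from .ac_estimation import AlleleConcentrationEstimate, Probeset
from .errors import DuplicateIdError, FormatError
from .normalization import AdjustmentFactors, RawCNTrack
from .probe_model import ProbeRecord
from .segmentation import CNVCall

ANNOTATION_COLUMNS = [
    "probe_id",
    "probeset_id",
    "target_allele",
    "sequence",
    "chrom",
    "position",
    "fragment_id",
]

CONCENTRATION_COLUMNS = [
    "probeset_id",
    "chrom",
    "position",
    "N_A",
    "N_B",
    "N_total",
    "background",
    "residual_sd",
    "clipped",
]

CALL_COLUMNS = ["sample_id", "chrom", "start", "end", "copy_state", "n_probes"]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------


def read_probe_annotation(path) -> list[Probeset]:
    """Read and validate a probe annotation TSV, grouped into probesets.

    Output probesets are sorted by (chrom, position); a probeset is SNP if
    it contains allele-targeted probes and NP otherwise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ANNOTATION_COLUMNS, path)
    return probesets_from_frame(df, source=path)


def probesets_from_frame(df: pd.DataFrame, source="annotation") -> list[Probeset]:
    """Group an annotation DataFrame (simulator output or file) into probesets."""
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise DuplicateIdError(f"{source}: duplicate probe_id {dup!r}")
    probes = [
        ProbeRecord(
            probe_id=r.probe_id,
            probeset_id=r.probeset_id,
            target_allele=r.target_allele,
            sequence=r.sequence,
            chrom=r.chrom,
            position=int(r.position),
            fragment_id=r.fragment_id,
        )
        for r in df.itertuples()
    ]
    by_set: dict[str, list[ProbeRecord]] = {}
    for p in probes:
        by_set.setdefault(p.probeset_id, []).append(p)
    probesets = []
    for pid, ps in by_set.items():
        alleles = {p.target_allele for p in ps}
        locus_type = "NP" if alleles == {"NP"} else "SNP"
        probesets.append(
            Probeset(
                probeset_id=pid,
                locus_type=locus_type,
                probes=ps,
                chrom=ps[0].chrom,
                position=ps[0].position,
            )
        )
    probesets.sort(key=lambda s: (s.chrom, s.position, s.probeset_id))
    return probesets


def write_probe_annotation(probesets, path) -> None:
    rows = [
        (p.probe_id, p.probeset_id, p.target_allele, p.sequence, p.chrom,
         p.position, p.fragment_id)
        for ps in probesets
        for p in ps.probes
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# intensity matrix
# ---------------------------------------------------------------------------


def read_intensity_matrix(path) -> pd.DataFrame:
    """Probes x samples intensity TSV (first column probe_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "probe_id":
        raise FormatError(f"{path}: first column must be probe_id")
    if df.shape[1] < 1:
        raise FormatError(f"{path}: no sample columns")
    if not np.all(np.isfinite(df.to_numpy())):
        raise FormatError(f"{path}: non-finite intensities")
    return df


def write_intensity_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# concentrations
# ---------------------------------------------------------------------------


def write_concentrations(estimates, path) -> None:
    rows = [
        (e.probeset_id, e.chrom, e.position, e.N_A, e.N_B, e.N_total,
         e.background, e.residual_sd, int(e.clipped))
        for e in estimates
    ]
    pd.DataFrame(rows, columns=CONCENTRATION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_concentrations(path) -> list[AlleleConcentrationEstimate]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CONCENTRATION_COLUMNS, path)
    return [
        AlleleConcentrationEstimate(
            probeset_id=str(r.probeset_id),
            sample_id="",
            N_A=float(r.N_A),
            N_B=float(r.N_B),
            background=float(r.background),
            residual_sd=float(r.residual_sd),
            clipped=bool(r.clipped),
            chrom=str(r.chrom),
            position=int(r.position),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# raw CN tracks and factors
# ---------------------------------------------------------------------------


def write_track_bedgraph(track: RawCNTrack, path) -> None:
    """Single-position 0-based half-open intervals, no track line."""
    with open(path, "w") as fh:
        for (pid, chrom, pos), value in zip(track.loci, track.values):
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{float(value)!r}\n")


def write_track_tsv(track: RawCNTrack, path) -> None:
    pd.DataFrame(
        {
            "probeset_id": [pid for pid, _, _ in track.loci],
            "chrom": [c for _, c, _ in track.loci],
            "position": [p for _, _, p in track.loci],
            "raw_cn": track.values,
        }
    ).to_csv(path, sep="\t", index=False)


def read_track_tsv(path, sample_id: str = "") -> RawCNTrack:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["probeset_id", "chrom", "position", "raw_cn"], path)
    loci = list(
        zip(df["probeset_id"].astype(str), df["chrom"].astype(str),
            df["position"].astype(int))
    )
    return RawCNTrack(
        sample_id=sample_id, loci=loci, values=df["raw_cn"].to_numpy(dtype=float)
    )


def write_adjustment_factors(factors: AdjustmentFactors, path) -> None:
    pd.DataFrame(
        {
            "probeset_id": [pid for pid, _, _ in factors.loci],
            "gamma": factors.gamma,
        }
    ).to_csv(path, sep="\t", index=False)


def read_adjustment_factors(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["probeset_id", "gamma"], path)
    return dict(zip(df["probeset_id"].astype(str), df["gamma"].astype(float)))


# ---------------------------------------------------------------------------
# CNV calls and regions
# ---------------------------------------------------------------------------


def write_calls(calls, path) -> None:
    """6-column TSV, BED-compatible 0-based half-open coordinates."""
    rows = [
        (c.sample_id, c.chrom, c.start, c.end, c.copy_state, c.n_probes)
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list[CNVCall]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CALL_COLUMNS, path)
    return [
        CNVCall(
            sample_id=str(r.sample_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            copy_state=int(r.copy_state),
            n_probes=int(r.n_probes),
            mean_raw_cn=math.nan,
        )
        for r in df.itertuples()
    ]


def write_regions(regions, path) -> None:
    """BED-like TSV: chrom, start, end, label."""
    from .evaluation import as_region

    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlabel\n")
        for r in regions:
            r = as_region(r)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


def read_regions(path) -> list:
    from .evaluation import Region

    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["chrom", "start", "end"], path)
    label = df["label"] if "label" in df.columns else [""] * len(df)
    return [
        Region(str(c), int(s), int(e), "" if pd.isna(l) else str(l))
        for c, s, e, l in zip(df["chrom"], df["start"], df["end"], label)
    ]


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
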