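"""Tabular file formats: probe panels, log-ratio matrices, genotype
tracks, segment matrices and YAML run configuration.

All tables are UTF-8 TSV with a header line; '#'-prefixed comment lines
are permitted. Intervals are 0-based half-open internally and in BED
exports. Round trips through every writer/reader pair are lossless.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotyping import ChromosomeCall, GenotypeParams, GenotypeTrack
from .panel import SPECIES, ProbePanel
from .segmentation import SegmentMatrix
from .simulate import IncompatibilitySpec, SimParams

logger = logging.getLogger(__name__)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# probe panels

def write_probe_panel(panel: ProbePanel, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        lengths = ",".join(f"{c}:{l}" for c, l in
                           sorted(panel.chromosome_lengths.items()))
        fh.write(f"# chromosome_lengths={lengths}\n")
        panel.probes.to_csv(fh, sep="\t", index=False)


def read_probe_panel(path) -> ProbePanel:
    path = Path(path)
    lengths: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "chromosome_lengths=" in line:
                spec = line.split("chromosome_lengths=", 1)[1].strip()
                for item in spec.split(","):
                    c, l = item.split(":")
                    lengths[int(c)] = int(l)
    df = _read_tsv(path)
    required = ["probe_id", "species", "chrom", "pos"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"panel header must start with {required}, "
                         f"got {list(df.columns)}")
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        if row.species not in SPECIES:
            raise ValueError(
                f"{path}:{lineno}: unknown species {row.species!r}")
    dup = df["probe_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate probe_id {df.loc[dup, 'probe_id'].iloc[0]!r}")
    df = df.sort_values(["species", "chrom", "pos"], kind="stable",
                        ignore_index=True)
    if not lengths:
        for chrom, grp in df.groupby("chrom"):
            gaps = np.diff(np.sort(grp["pos"].unique()))
            spacing = float(np.median(gaps)) if len(gaps) else 2000.0
            lengths[int(chrom)] = int(grp["pos"].max() + spacing)
        logger.info("panel %s lacks chromosome lengths; inferred from probes",
                    path)
    return ProbePanel(probes=df, chromosome_lengths=lengths)


def write_probe_panel_bed(panel: ProbePanel, path, probe_len: int = 60) -> None:
    """BED export (0-based half-open); name=probe_id, score unused."""
    with open(path, "w") as fh:
        for row in panel.probes.itertuples(index=False):
            fh.write(f"chr{row.chrom}\t{row.pos}\t{row.pos + probe_len}"
                     f"\t{row.probe_id}\t0\t.\n")


def read_probe_panel_bed(path, chromosome_lengths: dict[int, int]) -> ProbePanel:
    """Import a panel from BED; species parsed from the probe name prefix."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: need >= 4 BED columns")
            chrom = int(parts[0].removeprefix("chr"))
            start = int(parts[1])
            name = parts[3]
            species = name.split("_", 1)[0]
            if species not in SPECIES:
                raise ValueError(
                    f"{path}:{lineno}: cannot parse species from {name!r}")
            rows.append((name, species, chrom, start))
    df = pd.DataFrame(rows, columns=["probe_id", "species", "chrom", "pos"])
    df = df.sort_values(["species", "chrom", "pos"], kind="stable",
                        ignore_index=True)
    return ProbePanel(probes=df, chromosome_lengths=dict(chromosome_lengths))


# ---------------------------------------------------------------------------
# log-ratio matrices

def write_logratio_matrix(logratios: np.ndarray, panel: ProbePanel,
                          spore_ids: list[str], path) -> None:
    df = pd.DataFrame(logratios, columns=spore_ids)
    df.insert(0, "probe_id", panel.probes["probe_id"].to_numpy())
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_logratio_matrix(path, panel: ProbePanel
                         ) -> tuple[np.ndarray, list[str]]:
    """Load a probes x spores matrix aligned to ``panel`` row order.

    Probes absent from the file are NaN for every spore (logged once) and
    excluded downstream; rows not in the panel are rejected, as is a
    transposed file (spore columns colliding with probe ids).
    """
    df = _read_tsv(path)
    if df.columns[0] != "probe_id":
        raise ValueError("first column must be 'probe_id'")
    panel_ids = panel.probes["probe_id"]
    known = set(panel_ids)
    colliding = [c for c in df.columns[1:] if c in known]
    if colliding:
        raise ValueError(
            f"spore columns collide with probe ids ({colliding[:3]}...); "
            "is the matrix transposed?")
    unknown = set(df["probe_id"]) - known
    if unknown:
        raise ValueError(f"matrix rows not in panel: {sorted(unknown)[:5]}")
    spore_ids = list(df.columns[1:])
    values = df.set_index("probe_id")[spore_ids]
    if not np.issubdtype(values.to_numpy().dtype, np.number):
        bad = values.apply(pd.to_numeric, errors="coerce")
        r, c = np.argwhere(bad.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at probe {values.index[r]!r}, "
            f"spore {spore_ids[c]!r}")
    aligned = values.reindex(panel_ids)
    n_missing = int(aligned.isna().all(axis=1).sum())
    if n_missing:
        logger.warning("%d panel probes missing from matrix; marked missing",
                       n_missing)
    return aligned.to_numpy(dtype=float), spore_ids


# ---------------------------------------------------------------------------
# genotype tracks

def write_genotype_tracks(tracks: list[GenotypeTrack], path) -> None:
    """Regions + aneuploidy flags as one TSV (bp-resolved via the panel
    happens at read time; region bounds here are probe indices)."""
    rows = []
    for t in tracks:
        for (species, chrom), call in sorted(t.chromosomes.items()):
            for start, end, value in call.regions:
                rows.append({"spore": t.spore_id, "species": species,
                             "chrom": chrom, "start_idx": start,
                             "end_idx": end, "call": value,
                             "absent": int(call.absent),
                             "aneuploid": int(t.aneuploid.get(chrom, False))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_breakpoints(tracks: list[GenotypeTrack], path) -> None:
    rows = []
    for t in tracks:
        for (species, chrom), call in sorted(t.chromosomes.items()):
            for idx, bp in zip(call.breakpoints_idx, call.breakpoints_bp):
                rows.append({"spore": t.spore_id, "species": species,
                             "chrom": chrom, "boundary_idx": idx,
                             "pos_bp": bp})
    pd.DataFrame(rows, columns=["spore", "species", "chrom",
                                "boundary_idx", "pos_bp"]
                 ).to_csv(path, sep="\t", index=False)


def read_genotype_tracks(path, panel: ProbePanel) -> list[GenotypeTrack]:
    """Rebuild tracks from a regions TSV; probe calls are regenerated from
    the region majorities and breakpoints from the region borders."""
    df = _read_tsv(path)
    tracks = []
    for spore, sdf in df.groupby("spore", sort=False):
        chromosomes: dict[tuple[str, int], ChromosomeCall] = {}
        aneuploid: dict[int, bool] = {}
        for (species, chrom), cdf in sdf.groupby(["species", "chrom"]):
            cdf = cdf.sort_values("start_idx")
            positions = panel.positions(species, chrom)
            n = len(positions)
            calls = np.zeros(n, dtype=np.int8)
            regions = []
            for row in cdf.itertuples(index=False):
                calls[row.start_idx:row.end_idx] = row.call
                regions.append((int(row.start_idx), int(row.end_idx),
                                int(row.call)))
            bps = [r[0] for r in regions[1:]]
            chromosomes[(species, int(chrom))] = ChromosomeCall(
                species=species, chrom=int(chrom), calls=calls,
                absent=bool(cdf["absent"].iloc[0]), regions=regions,
                breakpoints_idx=bps,
                breakpoints_bp=[float((positions[b - 1] + positions[b]) / 2)
                                for b in bps])
            aneuploid[int(chrom)] = bool(cdf["aneuploid"].iloc[0])
        tracks.append(GenotypeTrack(spore_id=str(spore),
                                    chromosomes=chromosomes,
                                    aneuploid=aneuploid))
    return tracks


# ---------------------------------------------------------------------------
# segment matrices

def write_segment_matrix(matrix: SegmentMatrix, path) -> None:
    ids = matrix.segment_ids()
    df = pd.DataFrame(matrix.scores.astype(object), columns=ids)
    df = df.mask(df == -1, "NA")
    df.insert(0, "spore", matrix.spore_ids)
    df.to_csv(path, sep="\t", index=False)


def read_segment_matrix(path) -> SegmentMatrix:
    df = _read_tsv(path)
    if df.columns[0] != "spore":
        raise ValueError("first column must be 'spore'")
    ids = list(df.columns[1:])
    genome = ids[0].split(":")[0]
    seg_rows = []
    for sid in ids:
        g, chrom, span = sid.split(":")
        if g != genome:
            raise ValueError("mixed genomes in one segment matrix")
        start, end = span.split("-")
        seg_rows.append((int(chrom), float(start), float(end)))
    segments = pd.DataFrame(seg_rows, columns=["chrom", "start", "end"])
    raw = df[ids].to_numpy()                  # "NA" cells parse as NaN
    raw = np.where(pd.isna(raw), -1, raw)
    scores = raw.astype(float).astype(np.int8)
    return SegmentMatrix(genome=genome, segments=segments, scores=scores,
                         spore_ids=[str(s) for s in df["spore"]])


def write_segments_bed(matrix: SegmentMatrix, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(matrix.segment_ids(),
                            matrix.segments.itertuples(index=False)):
            fh.write(f"chr{int(row.chrom)}\t{int(row.start)}\t{int(row.end)}"
                     f"\t{sid}\t0\t.\n")


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class ScanConfig:
    fdr_threshold: float = 0.01
    n_perm: int = 1000
    interchromosomal_only: bool = True
    max_triples: int = 10_000_000
    triple_n_perm: int = 20
    merge_tol_bp: float = 2_000.0


@dataclass
class RunConfig:
    """Everything a pipeline run needs, round-trippable through YAML."""

    sim: SimParams = field(default_factory=SimParams)
    incompatibilities: list[IncompatibilitySpec] = field(default_factory=list)
    genotype: GenotypeParams = field(default_factory=GenotypeParams)
    scan: ScanConfig = field(default_factory=ScanConfig)
    seed: int = 0


def save_config(config: RunConfig, path) -> None:
    doc = {
        "seed": config.seed,
        "sim": asdict(config.sim),
        "incompatibilities": [
            {"loci": [list(l) for l in s.loci],
             "lethal_patterns": [list(p) for p in s.lethal_patterns],
             "penetrance": s.penetrance}
            for s in config.incompatibilities],
        "genotype": asdict(config.genotype),
        "scan": asdict(config.scan),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    sim_kw = dict(doc.get("sim", {}))
    if "chromosome_lengths" in sim_kw:
        sim_kw["chromosome_lengths"] = {
            int(k): int(v) for k, v in sim_kw["chromosome_lengths"].items()}
    specs = [IncompatibilitySpec(
                loci=[tuple(l) for l in s["loci"]],
                lethal_patterns=[tuple(p) for p in s["lethal_patterns"]],
                penetrance=float(s.get("penetrance", 1.0)))
             for s in doc.get("incompatibilities", [])]
    return RunConfig(
        sim=SimParams(**sim_kw),
        incompatibilities=specs,
        genotype=GenotypeParams(**doc.get("genotype", {})),
        scan=ScanConfig(**doc.get("scan", {})),
        seed=int(doc.get("seed", 0)),
    )
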