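"""Synthetic gemmae, profile sets, toy genomes and expression tables.

Every downstream stage of the package is testable offline against planted
ground truth produced here:

* :func:`make_profile_set` — profile matrices drawn from domain archetypes
  with multiplicative Gaussian noise (the field's standard model for
  signal-proportional fluorescence variation);
* :func:`make_gemma_image` — two-channel images of a lenticular gemma
  (ellipse, aspect 1.3:1, two wedge notches on the major axis) with nuclear
  reporter spots whose brightness follows an archetype along the notch axis,
  under Poisson shot noise plus additive Gaussian read noise;
* :func:`make_toy_genome` — small annotated genomes with controlled 5'UTR
  lengths, planted Type IIS recognition sites and N-runs at recorded
  positions;
* :func:`make_expression_table` — per-gene TPM and expressing-cell counts
  whose class-wise asinh means match planted values.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .archetypes import DomainArchetype, standard_archetypes, DEFAULT_NOTCH
from .catalog import CATEGORIES, ReporterRecord
from .imaging import GemmaImage, LandmarkSet
from .parts import ENZYMES, _revcomp, scan_sites

__all__ = [
    "NoiseParams",
    "SyntheticGemmaTruth",
    "ToyGenome",
    "PlantedSite",
    "make_profile_set",
    "make_gemma_image",
    "make_toy_genome",
    "make_expression_table",
]


# ---------------------------------------------------------------------------
# profile sets


def make_profile_set(
    archetypes: list[DomainArchetype] | dict[str, DomainArchetype] | None = None,
    n_per_archetype: int = 40,
    noise_sd: float = 0.1,
    grid_n: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Profile matrix with rows ``archetype(x) * (1 + eps)``, eps ~ N(0, sd).

    Returns the matrix (rows grouped by archetype, on the full [0, 1] grid)
    and the planted archetype labels.  Noise is clipped so intensities stay
    nonnegative.
    """
    if archetypes is None:
        archetypes = standard_archetypes()
    if isinstance(archetypes, dict):
        archetypes = list(archetypes.values())
    if not archetypes:
        raise ValueError("empty archetype list")
    if not np.isfinite(noise_sd) or noise_sd < 0:
        raise ValueError("noise_sd must be finite and >= 0")
    if n_per_archetype < 1:
        raise ValueError("n_per_archetype must be >= 1")
    if grid_n < 16:
        raise ValueError("grid_n must be >= 16")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, grid_n)
    rows, labels, ids = [], [], []
    for arch in archetypes:
        clean = arch(x)
        for i in range(n_per_archetype):
            eps = rng.normal(0.0, noise_sd, size=grid_n) if noise_sd > 0 else 0.0
            rows.append(np.clip(clean * (1.0 + eps), 0.0, None))
            labels.append(arch.name)
            ids.append(f"{arch.name}_{i}")
    matrix = pd.DataFrame(np.vstack(rows), index=ids, columns=np.round(x, 6))
    return matrix, np.asarray(labels)


# ---------------------------------------------------------------------------
# gemma images


@dataclass(frozen=True)
class NoiseParams:
    """Poisson-Gaussian imaging noise: shot noise at ``photons`` quanta per
    intensity unit (None disables it) plus additive read noise of sd ``read_sd``."""

    photons: float | None = 100.0
    read_sd: float = 0.01

    @classmethod
    def none(cls) -> "NoiseParams":
        return cls(photons=None, read_sd=0.0)


@dataclass
class SyntheticGemmaTruth:
    """Planted ground truth for one synthetic gemma image."""

    landmarks: LandmarkSet  # 2D pixel coordinates, pre-rotation convention
    mask: np.ndarray  # tissue mask (bool)
    nucleus_centers: np.ndarray  # (n, 2) as (x, y)
    nucleus_axis_positions: np.ndarray  # normalized axis position of each nucleus
    nucleus_amplitudes: np.ndarray  # planted archetype value per nucleus
    archetype: str
    notch: float
    seed: int


def _gemma_geometry(size: int, notch: float, angle: float):
    a = size / 2.0 - 3.0
    b = a / 1.3
    ex = a * abs(math.cos(angle)) + b * abs(math.sin(angle))
    ey = a * abs(math.sin(angle)) + b * abs(math.cos(angle))
    w = 2 * int(math.ceil(ex)) + 9
    h = 2 * int(math.ceil(ey)) + 9
    return a, b, w, h


def make_gemma_image(
    archetype: DomainArchetype | str,
    size: int = 384,
    n_nuclei: int = 2600,
    noise: NoiseParams | None = None,
    seed: int = 0,
    notch: float = DEFAULT_NOTCH,
    angle_deg: float = 0.0,
    nucleus_sigma: float = 2.5,
    rim_compensation: bool = True,
) -> tuple[GemmaImage, SyntheticGemmaTruth]:
    """Render a two-channel synthetic gemma with planted reporter amplitudes.

    The tissue is an ellipse (aspect 1.3:1) with two wedge notches on the
    major axis; nuclei sit on a jittered grid inside the tissue and their
    planted brightness is the archetype evaluated at the nucleus's normalized
    axis position.  With ``rim_compensation`` (default) the rendered spot
    amplitude additionally carries the inverse of the local tissue chord
    length, so that the rectangular per-column-mean profile convention
    recovers the planted 1D field exactly; switch it off for optically
    realistic (uncompensated) images.  ``angle_deg`` tilts the notch axis to
    exercise the rotation stage.
    """
    if isinstance(archetype, str):
        archetype = standard_archetypes(notch)[archetype]
    if size < 128:
        raise ValueError("size must be >= 128 px along the notch axis")
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    noise = noise if noise is not None else NoiseParams.none()
    rng = np.random.default_rng(seed)
    phi = math.radians(angle_deg)
    a, b, w, h = _gemma_geometry(size, notch, phi)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0

    # frame coordinates: u along the notch axis, v across it
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    cosp, sinp = math.cos(phi), math.sin(phi)
    fu = dx * cosp + dy * sinp
    fv = -dx * sinp + dy * cosp

    start_u, end_u = -0.84 * a, 0.84 * a
    axis_len = end_u - start_u
    notch1_u = start_u + notch * axis_len
    notch2_u = start_u + (1.0 - notch) * axis_len

    mask = (fu / a) ** 2 + (fv / b) ** 2 <= 1.0
    slope = 0.35
    mask &= ~((fu < notch1_u) & (np.abs(fv) < slope * (notch1_u - fu)))
    mask &= ~((fu > notch2_u) & (np.abs(fv) < slope * (fu - notch2_u)))

    # nuclei on a jittered grid, kept clear of the tissue border
    area = float(mask.sum())
    spacing = math.sqrt(area / n_nuclei)
    dist = ndimage.distance_transform_edt(mask)
    gx = np.arange(0, w, spacing)
    gy = np.arange(0, h, spacing)
    px, py = np.meshgrid(gx, gy)
    px = (px + rng.uniform(-0.2, 0.2, px.shape) * spacing).ravel()
    py = (py + rng.uniform(-0.2, 0.2, py.shape) * spacing).ravel()
    ix = np.clip(np.round(px).astype(int), 0, w - 1)
    iy = np.clip(np.round(py).astype(int), 0, h - 1)
    keep = dist[iy, ix] >= 1.5 * nucleus_sigma
    px, py = px[keep], py[keep]
    if px.size == 0:
        raise ValueError("no nuclei fit inside the tissue; increase size or n_nuclei")

    nu = (px - cx) * cosp + (py - cy) * sinp
    axis_pos = (nu - start_u) / axis_len
    planted = archetype(axis_pos)

    def render(amps: np.ndarray) -> np.ndarray:
        canvas = np.zeros((h, w))
        win = int(math.ceil(4 * nucleus_sigma))
        for x0, y0, amp in zip(px, py, amps):
            xi, yi = int(round(x0)), int(round(y0))
            sl = np.s_[
                max(yi - win, 0) : min(yi + win + 1, h),
                max(xi - win, 0) : min(xi + win + 1, w),
            ]
            gy2, gx2 = np.mgrid[sl]
            canvas[sl] += amp * np.exp(
                -((gx2 - x0) ** 2 + (gy2 - y0) ** 2) / (2 * nucleus_sigma**2)
            )
        return canvas

    amps = planted.copy()
    if rim_compensation:
        # normalize each nucleus by the realized unit spot mass of its column,
        # so the rectangular column-mean convention recovers the planted field
        unit_cols = render(np.ones_like(planted)).sum(axis=0)
        ref_mass = float(np.median(unit_cols[unit_cols > 0]))
        ixn = np.clip(np.round(px).astype(int), 0, w - 1)
        comp = ref_mass / np.maximum(unit_cols[ixn], ref_mass / 5.0)
        amps = amps * comp

    reporter = render(amps)

    outline = mask & ~ndimage.binary_erosion(mask, iterations=2)
    membrane = np.where(outline, 1.0, 0.0) + np.where(mask, 0.15, 0.0)

    if noise.photons is not None and noise.photons > 0:
        reporter = rng.poisson(reporter * noise.photons) / noise.photons
        membrane = rng.poisson(membrane * noise.photons) / noise.photons
    if noise.read_sd > 0:
        reporter = reporter + rng.normal(0.0, noise.read_sd, reporter.shape)
        membrane = membrane + rng.normal(0.0, noise.read_sd, membrane.shape)
    reporter = np.clip(reporter, 0.0, None)
    membrane = np.clip(membrane, 0.0, None)

    def to_xy(u: float) -> tuple[float, float]:
        return (cx + u * cosp, cy + u * sinp)

    landmarks = LandmarkSet(
        to_xy(start_u), to_xy(notch1_u), to_xy(notch2_u), to_xy(end_u)
    )
    truth = SyntheticGemmaTruth(
        landmarks=landmarks,
        mask=mask,
        nucleus_centers=np.column_stack([px, py]),
        nucleus_axis_positions=axis_pos,
        nucleus_amplitudes=planted,
        archetype=archetype.name,
        notch=notch,
        seed=seed,
    )
    image = GemmaImage({"reporter": reporter, "membrane": membrane})
    return image, truth


# ---------------------------------------------------------------------------
# toy genomes


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    enzyme: str
    genomic_pos: int  # 1-based plus-strand start of the recognition footprint
    part_offset: int  # 1-based start within the PROM part (part orientation)
    strand: str


@dataclass
class ToyGenome:
    """An in-memory toy genome with its annotation and planted-feature record."""

    sequences: dict[str, str]
    gff_text: str
    gene_ids: list[str]
    utr_lengths: dict[str, int]
    strands: dict[str, str]
    planted_sites: list[PlantedSite]
    planted_n_runs: list[tuple[str, int, int]]  # (gene_id, genomic start, run length)
    seed: int

    @property
    def fasta_text(self) -> str:
        buf = io.StringIO()
        for name, seq in self.sequences.items():
            buf.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                buf.write(seq[i : i + 80] + "\n")
        return buf.getvalue()

    def write(self, out_dir) -> tuple[Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta = out / "toy_genome.fa"
        gff = out / "toy_genome.gff3"
        fasta.write_text(self.fasta_text)
        gff.write_text(self.gff_text)
        return fasta, gff


def _protected_span(protected: set[int]) -> set[int]:
    span = set()
    for p in protected:
        span.update(range(p, p + 7))
    return span


def make_toy_genome(
    utr_lengths: list[int],
    plant_sites: dict[int, list[tuple[str, int]]] | None = None,
    plant_n_runs: dict[int, tuple[int, int]] | None = None,
    seed: int = 0,
    upstream_margin: int = 2500,
    cds_len: int = 300,
) -> ToyGenome:
    """One gene per 5'UTR length on a single random contig, half minus-strand.

    ``plant_sites[i]`` is a list of ``(enzyme, offset)`` pairs: the
    recognition string is written on the coding strand of gene ``i`` with its
    TSS-proximal end ``offset`` bp upstream of the TSS.  ``plant_n_runs[i]``
    is ``(offset, run_length)``: a run of N placed the same way.  Outside the
    planted footprints the contig is guaranteed free of BsaI/SapI sites, so a
    scan finds exactly the planted occurrences.
    """
    if not utr_lengths:
        raise ValueError("utr_lengths must be nonempty")
    if any(u < 0 for u in utr_lengths):
        raise ValueError("utr_lengths entries must be >= 0")
    plant_sites = plant_sites or {}
    plant_n_runs = plant_n_runs or {}
    for i, spec in plant_sites.items():
        for enzyme, offset in spec:
            if enzyme not in ENZYMES:
                raise ValueError(f"unknown enzyme {enzyme!r}")
            if not len(ENZYMES[enzyme]) <= offset <= upstream_margin - 10:
                raise ValueError("planted-site offset outside the upstream window")
    for i, (offset, run) in plant_n_runs.items():
        if offset + run > upstream_margin - 10:
            raise ValueError("intergenic spacing too small for the requested N-run offset")

    rng = np.random.default_rng(seed)
    blocks = [upstream_margin + u + cds_len + 200 for u in utr_lengths]
    total = sum(blocks) + 200
    seq = list("".join(rng.choice(list("ACGT"), size=total)))

    gene_ids = [f"gene{i+1:03d}" for i in range(len(utr_lengths))]
    strands = {gid: ("+" if i % 2 == 0 else "-") for i, gid in enumerate(gene_ids)}

    features = []
    tss_pos: dict[str, int] = {}
    pos = 0  # 0-based block start
    coords: dict[str, dict] = {}
    for i, (gid, utr) in enumerate(zip(gene_ids, utr_lengths)):
        strand = strands[gid]
        if strand == "+":
            tss = pos + upstream_margin + 1  # 1-based
            utr_iv = (tss, tss + utr - 1) if utr > 0 else None
            cds_iv = (tss + utr, tss + utr + cds_len - 1)
            gene_iv = (tss, cds_iv[1])
        else:
            cds_iv = (pos + 201, pos + 200 + cds_len)
            utr_iv = (cds_iv[1] + 1, cds_iv[1] + utr) if utr > 0 else None
            tss = cds_iv[1] + utr
            gene_iv = (cds_iv[0], tss)
        tss_pos[gid] = tss
        coords[gid] = {"gene": gene_iv, "utr": utr_iv, "cds": cds_iv, "strand": strand}
        pos += blocks[i]

    # plant requested features (0-based indices into seq)
    planted_sites: list[PlantedSite] = []
    protected: set[int] = set()
    for i, spec in plant_sites.items():
        gid = gene_ids[i]
        strand = strands[gid]
        tss = tss_pos[gid]
        for enzyme, offset in spec:
            site = ENZYMES[enzyme]
            m = len(site)
            if strand == "+":
                g0 = tss - offset - 1  # 0-based footprint start
                written = site
            else:
                g0 = tss + offset - m  # footprint [tss+offset-m+1, tss+offset]
                written = _revcomp(site)
            seq[g0 : g0 + m] = list(written)
            protected.add(g0)
            part_offset = 1800 - offset + 1
            planted_sites.append(PlantedSite(gid, enzyme, g0 + 1, part_offset, strand))

    planted_runs: list[tuple[str, int, int]] = []
    for i, (offset, run) in plant_n_runs.items():
        gid = gene_ids[i]
        tss = tss_pos[gid]
        if strands[gid] == "+":
            g0 = tss - offset - 1
        else:
            g0 = tss + offset - run
        seq[g0 : g0 + run] = list("N" * run)
        planted_runs.append((gid, g0 + 1, run))

    n_positions = {i for (_, g0, run) in planted_runs for i in range(g0 - 1, g0 - 1 + run)}
    _scrub_with_ns(seq, protected, n_positions)

    # GFF3
    lines = ["##gff-version 3", f"##sequence-region chr1 1 {total}"]
    for gid in gene_ids:
        c = coords[gid]
        s = c["strand"]
        g0, g1 = c["gene"]
        lines.append(f"chr1\ttoy\tgene\t{g0}\t{g1}\t.\t{s}\t.\tID={gid}")
        lines.append(f"chr1\ttoy\tmRNA\t{g0}\t{g1}\t.\t{s}\t.\tID={gid}.1;Parent={gid}")
        if c["utr"]:
            u0, u1 = c["utr"]
            lines.append(
                f"chr1\ttoy\tfive_prime_UTR\t{u0}\t{u1}\t.\t{s}\t.\tID={gid}.1.utr;Parent={gid}.1"
            )
        c0, c1 = c["cds"]
        lines.append(f"chr1\ttoy\tCDS\t{c0}\t{c1}\t.\t{s}\t0\tID={gid}.1.cds;Parent={gid}.1")
    gff_text = "\n".join(lines) + "\n"

    return ToyGenome(
        sequences={"chr1": "".join(seq)},
        gff_text=gff_text,
        gene_ids=gene_ids,
        utr_lengths=dict(zip(gene_ids, utr_lengths)),
        strands=strands,
        planted_sites=planted_sites,
        planted_n_runs=planted_runs,
        seed=seed,
    )


def _scrub_with_ns(seq: list[str], protected: set[int], n_positions: set[int]) -> None:
    """Scrub chance enzyme sites in place, never touching planted footprints or N-runs."""
    order = "ACGT"
    guard = _protected_span(protected) | n_positions
    for _ in range(500):
        text = "".join(seq)
        actionable = None
        for h in scan_sites(text):
            fp = list(range(h.position - 1, h.position - 1 + len(ENZYMES[h.enzyme])))
            if any(seq[i] == "N" for i in fp):
                continue  # N interrupts any real site
            free = [i for i in fp if i not in guard]
            if not free:
                continue  # the planted site itself
            # prefer the 3rd footprint base when it is free
            idx = fp[2] if fp[2] in free else free[0]
            actionable = idx
            break
        if actionable is None:
            return
        seq[actionable] = order[(order.index(seq[actionable]) + 1) % 4]
    raise RuntimeError("could not scrub chance enzyme sites")


# ---------------------------------------------------------------------------
# expression tables

# precedence used to pick the class whose planted mean a multi-flag record follows
_CLASS_PRECEDENCE = ("ubiquitous", "specialized", "notch", "dim", "no_signal")


def make_expression_table(
    records: list[ReporterRecord],
    class_means: dict[str, float],
    seed: int = 0,
    sd: float = 0.3,
    cell_means: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-gene TPM and expressing-cell counts with planted class-wise asinh means.

    For each record's class (first match in the precedence ubiquitous >
    specialized > notch > dim > no_signal) an asinh-scale value a ~ N(mean,
    sd) is drawn and back-transformed, TPM = sinh(a); expressing-cell counts
    follow the same scheme (rounded).  With ``sd = 0`` the asinh of every
    sampled value equals the planted class mean exactly.
    """
    unknown = set(class_means) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown category names: {sorted(unknown)}")
    if not all(np.isfinite(v) for v in class_means.values()):
        raise ValueError("class means must be finite")
    if any(v < 0 for v in class_means.values()):
        raise ValueError("class means must be >= 0 on the asinh scale")
    cell_means = cell_means or class_means
    rng = np.random.default_rng(seed)
    rows = []
    for rec in records:
        cls = next((c for c in _CLASS_PRECEDENCE if c in rec.categories), None)
        if cls is None or cls not in class_means:
            raise ValueError(f"record {rec.gene_id}: no class mean for {sorted(rec.categories)}")
        a = max(class_means[cls] + (rng.normal(0.0, sd) if sd > 0 else 0.0), 0.0)
        b = max(cell_means[cls] + (rng.normal(0.0, sd) if sd > 0 else 0.0), 0.0)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "tpm": math.sinh(a),
                "n_cells": int(round(math.sinh(b))),
                "true_class": cls,
            }
        )
    return pd.DataFrame(rows)
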