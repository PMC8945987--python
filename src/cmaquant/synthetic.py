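"""Synthetic data with ground truth for every pipeline stage.

Three generators emulate the study's inputs so the downstream code is
testable without the original (undeposited) raw data:

* :func:`gen_quant_table` — SILAC-style protein quantification tables
  with planted two-fold up/down regulation, replicate-derived p-values,
  peptide counts and confidence tiers;
* :func:`gen_motif_proteins` — protein sequences carrying one planted
  KFERQ-like motif of a chosen class on a motif-free background;
* :func:`gen_cell_image` — two-channel (nuclei + reporter) fluorescence
  images with disk nuclei, watershed-separable cells, Gaussian-spot
  puncta of known per-cell counts, and additive noise at controlled SNR
  (spot amplitude / noise standard deviation).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import motifs
from .silac import DEFAULT_COLUMN_MAP

# ---------------------------------------------------------------------------
# Quantification tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantTruth:
    """Planted regulation status of one synthetic protein."""

    protein_id: str
    planted_label: str  # up | down | null
    true_log2_effect: float


def gen_quant_table(
    n_proteins: int,
    frac_up: float = 0.2,
    frac_down: float = 0.2,
    n_replicates: int = 3,
    rep_sd: float = 0.2,
    seed: int = 0,
    treatment: str = "PA",
    frac_high_confidence: float = 0.9,
) -> tuple[pd.DataFrame, list[QuantTruth]]:
    """Simulate a Proteome Discoverer-style quantification export.

    Each protein receives a true log2 effect (up: uniform on [1, 2.5];
    down: on [-2.5, -1]; null: 0) and ``n_replicates`` replicate
    log2-ratios drawn around it with standard deviation ``rep_sd``
    (mirrors a three-technical-replicate design).  The reported ratio is
    2**(mean log2-ratio); the p-value is a two-sided one-sample t-test
    of the replicates against 0, so ratio and p are jointly realistic.
    Peptide counts are 1 + Poisson(4); the confidence tier is "high"
    with probability ``frac_high_confidence``.
    """
    if frac_up < 0 or frac_down < 0 or frac_up + frac_down > 1:
        raise ValueError("frac_up and frac_down must be non-negative and sum to <= 1")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates for a t-test")
    rng = np.random.default_rng(seed)

    n_up = int(round(n_proteins * frac_up))
    n_down = int(round(n_proteins * frac_down))
    labels = ["up"] * n_up + ["down"] * n_down + ["null"] * (n_proteins - n_up - n_down)
    rng.shuffle(labels)

    truths: list[QuantTruth] = []
    rows: list[dict] = []
    for i, label in enumerate(labels):
        if label == "up":
            effect = float(rng.uniform(1.0, 2.5))
        elif label == "down":
            effect = float(-rng.uniform(1.0, 2.5))
        else:
            effect = 0.0
        reps = effect + rng.normal(0.0, rep_sd, size=n_replicates)
        mean_log2 = float(np.mean(reps))
        if np.std(reps, ddof=1) < 1e-12:
            # Degenerate noise-free limit: the t statistic is +-inf (or 0/0).
            p_value = 0.0 if abs(mean_log2) > 1e-12 else 1.0
        else:
            p_value = float(stats.ttest_1samp(reps, 0.0).pvalue)
        protein_id = f"SYNP{i:05d}"
        truths.append(QuantTruth(protein_id, label, effect))
        rows.append(
            {
                DEFAULT_COLUMN_MAP["protein_id"]: protein_id,
                DEFAULT_COLUMN_MAP["gene_symbol"]: f"Gene{i}",
                DEFAULT_COLUMN_MAP["ratio"]: float(2.0**mean_log2),
                DEFAULT_COLUMN_MAP["p_value"]: p_value,
                DEFAULT_COLUMN_MAP["peptide_count"]: int(1 + rng.poisson(4.0)),
                DEFAULT_COLUMN_MAP["confidence"]: (
                    "high"
                    if rng.random() < frac_high_confidence
                    else ("medium" if rng.random() < 0.7 else "low")
                ),
                "Treatment": treatment,
            }
        )
    return pd.DataFrame(rows), truths


def write_quant_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Motif-bearing protein sequences
# ---------------------------------------------------------------------------

#: Residues outside every motif residue class (no F/I/L/V, K/R, D/E,
#: S/T/Y, Q), so a random background can never form an accidental motif.
SAFE_ALPHABET = "AGMPWC"


@dataclass(frozen=True)
class SequenceTruth:
    """A synthetic protein sequence and the motifs planted in it."""

    protein_id: str
    sequence: str
    planted_hits: tuple  # ((0-based position, motif class), ...)


def _sample_motif_window(rng: np.random.Generator, motif_class: str) -> str:
    """Draw one pentapeptide of the requested class (verified by rescan)."""
    phospho = motif_class in (motifs.CLASS_PHOSPHO, motifs.CLASS_PHOSPHO_ACETYL)
    acetyl = motif_class in (motifs.CLASS_ACETYL, motifs.CLASS_PHOSPHO_ACETYL)
    hyd = sorted(motifs.HYDROPHOBIC)
    bas = sorted(motifs.BASIC)
    aci = sorted(motifs.PHOSPHO_MIMIC if phospho else motifs.ACIDIC)
    for _ in range(100):
        n_h = int(rng.integers(1, 3))
        flanks = (
            [hyd[rng.integers(len(hyd))] for _ in range(n_h)]
            + [bas[rng.integers(len(bas))] for _ in range(3 - n_h)]
            + [aci[rng.integers(len(aci))]]
        )
        rng.shuffle(flanks)
        anchor = "K" if acetyl else "Q"
        window = "".join(flanks) + anchor if rng.random() < 0.5 else anchor + "".join(flanks)
        if motifs.classify_pentapeptide(window) == motif_class:
            return window
    raise RuntimeError(f"could not sample a {motif_class} window")  # pragma: no cover


def gen_motif_proteins(
    n_per_class: int,
    classes: Sequence[str] | None = None,
    length: int = 80,
    seed: int = 0,
    protein_ids: Sequence[str] | None = None,
) -> list[SequenceTruth]:
    """Generate sequences with exactly one planted motif per sequence
    (or none for the "none" class) on a motif-free background.

    Each emitted sequence is re-scanned and resampled until the observed
    hits equal the planted hits, so the truth is self-validating.  With
    ``protein_ids`` given, one sequence per id is produced and the motif
    classes are assigned round-robin across ``classes`` (``n_per_class``
    is ignored), which ties sequences to an existing quantification
    table.
    """
    if length < 5:
        raise ValueError("length must be >= 5 to hold a pentapeptide")
    if classes is None:
        classes = list(motifs.MOTIF_CLASSES) + ["none"]
    allowed = set(motifs.MOTIF_CLASSES) | {"none"}
    bad = set(classes) - allowed
    if bad:
        raise ValueError(f"unknown motif classes: {sorted(bad)}")

    rng = np.random.default_rng(seed)
    safe = np.array(list(SAFE_ALPHABET))
    if protein_ids is not None:
        assignments = [
            (pid, classes[i % len(classes)]) for i, pid in enumerate(protein_ids)
        ]
    else:
        assignments = [
            (f"SYN_{cls.replace('+', '_')}_{i:03d}", cls)
            for cls in classes
            for i in range(n_per_class)
        ]
    out: list[SequenceTruth] = []
    for protein_id, motif_class in assignments:
        for _ in range(100):
            background = "".join(rng.choice(safe, size=length))
            if motif_class == "none":
                sequence, planted = background, ()
            else:
                pos = int(rng.integers(0, length - 4))
                window = _sample_motif_window(rng, motif_class)
                sequence = background[:pos] + window + background[pos + 5 :]
                planted = ((pos, motif_class),)
            observed = tuple(
                (h.start, h.motif_class) for h in motifs.scan_sequence(sequence)
            )
            if observed == planted:
                out.append(SequenceTruth(protein_id, sequence, planted))
                break
        else:  # pragma: no cover - safe alphabet makes this unreachable
            raise RuntimeError(f"self-validation failed for {protein_id}")
    return out


def write_fasta(truths: Sequence[SequenceTruth], path) -> None:
    with open(path, "w") as fh:
        for t in truths:
            fh.write(f">{t.protein_id}\n{t.sequence}\n")


def write_sequence_truth(truths: Sequence[SequenceTruth], path) -> None:
    payload = {
        t.protein_id: [list(hit) for hit in t.planted_hits] for t in truths
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Two-channel cell images
# ---------------------------------------------------------------------------


@dataclass
class CellImage:
    """Two-channel intensity stack, shape (2, rows, cols), values in [0, 1]."""

    data: np.ndarray
    nuclei_channel: int = 0
    reporter_channel: int = 1


@dataclass
class ImageTruth:
    """Ground truth for one synthetic image."""

    nuclei_centers: list  # [(row, col), ...]
    cell_masks: list  # per-cell boolean arrays (disjoint)
    puncta: list  # per-cell [(row, col) sub-pixel centers]
    snr: float


def gen_cell_image(
    n_cells: int,
    puncta_per_cell: int | Sequence[int] = 8,
    spot_sigma: float = 1.5,
    snr: float = 10.0,
    size: tuple[int, int] = (512, 512),
    seed: int = 0,
    *,
    cell_radius: float = 26.0,
    nucleus_radius: float = 9.0,
    cyto_baseline: float = 0.08,
    noise_sd: float = 0.08,
    nuclei_noise_sd: float = 0.02,
    min_puncta_separation: float | None = None,
    poisson_noise: bool = False,
    max_tries: int = 5000,
) -> tuple[CellImage, ImageTruth]:
    """Render a two-channel field of cells with known puncta.

    Channel 0 holds DAPI-like nucleus disks; channel 1 a dim cytoplasm
    baseline plus Gaussian spots of amplitude ``snr * noise_sd`` and
    additive Gaussian read noise.  Cell disks are placed without
    overlap; puncta fall in the cytoplasm (outside the nucleus) with a
    minimum mutual separation of ``4 * spot_sigma`` by default.
    Intensities are clipped to [0, 1]; output is bit-identical for a
    fixed seed.  Raises ``RuntimeError`` if placement fails after
    bounded retries.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rows, cols = size
    rng = np.random.default_rng(seed)
    if np.isscalar(puncta_per_cell):
        puncta_counts = [int(puncta_per_cell)] * n_cells
    else:
        puncta_counts = [int(k) for k in puncta_per_cell]
        if len(puncta_counts) != n_cells:
            raise ValueError("per-cell puncta list length must equal n_cells")
    if min_puncta_separation is None:
        min_puncta_separation = 4.0 * spot_sigma

    margin = cell_radius + 2.0
    min_center_dist = 2.0 * cell_radius + 3.0
    if n_cells and (rows < 2 * margin or cols < 2 * margin):
        raise ValueError("image too small for the requested cell radius")

    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_cells:
        if tries >= max_tries:
            raise RuntimeError(
                f"placed only {len(centers)}/{n_cells} cells after {max_tries} tries"
            )
        tries += 1
        cand = (
            float(rng.uniform(margin, rows - margin)),
            float(rng.uniform(margin, cols - margin)),
        )
        if all(np.hypot(cand[0] - r, cand[1] - c) >= min_center_dist for r, c in centers):
            centers.append(cand)

    rr, cc = np.mgrid[0:rows, 0:cols]
    nuclei = np.zeros((rows, cols))
    reporter = np.zeros((rows, cols))
    cell_masks: list[np.ndarray] = []
    puncta: list[list[tuple[float, float]]] = []

    for (cy, cx), n_spots in zip(centers, puncta_counts):
        dist2 = (rr - cy) ** 2 + (cc - cx) ** 2
        cell = dist2 <= cell_radius**2
        nucleus = dist2 <= nucleus_radius**2
        cell_masks.append(cell)
        nuclei[nucleus] = 0.8
        reporter[cell] += cyto_baseline

        spots: list[tuple[float, float]] = []
        tries = 0
        r_lo, r_hi = nucleus_radius + 1.0, cell_radius - 3.0
        while len(spots) < n_spots:
            if tries >= max_tries:
                raise RuntimeError(
                    f"placed only {len(spots)}/{n_spots} puncta after {max_tries} tries"
                )
            tries += 1
            rad = float(np.sqrt(rng.uniform(r_lo**2, r_hi**2)))
            ang = float(rng.uniform(0.0, 2.0 * np.pi))
            pr, pc = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            if all(
                np.hypot(pr - qr, pc - qc) >= min_puncta_separation for qr, qc in spots
            ):
                spots.append((pr, pc))
        puncta.append(spots)

        amp = snr * noise_sd
        half = int(np.ceil(4.0 * spot_sigma))
        for pr, pc in spots:
            r0, r1 = max(0, int(pr) - half), min(rows, int(pr) + half + 1)
            c0, c1 = max(0, int(pc) - half), min(cols, int(pc) + half + 1)
            pr_grid, pc_grid = np.mgrid[r0:r1, c0:c1]
            reporter[r0:r1, c0:c1] += amp * np.exp(
                -((pr_grid - pr) ** 2 + (pc_grid - pc) ** 2) / (2.0 * spot_sigma**2)
            )

    if poisson_noise:
        scale = 1000.0
        reporter = rng.poisson(np.clip(reporter, 0, None) * scale) / scale
    nuclei = nuclei + rng.normal(0.0, nuclei_noise_sd, size=(rows, cols))
    reporter = reporter + rng.normal(0.0, noise_sd, size=(rows, cols))
    data = np.clip(np.stack([nuclei, reporter]), 0.0, 1.0).astype(np.float32)

    truth = ImageTruth(
        nuclei_centers=centers,
        cell_masks=cell_masks,
        puncta=puncta,
        snr=float(snr),
    )
    return CellImage(data=data), truth


def write_image_tiff(image: CellImage, path) -> None:
    import tifffile

    tifffile.imwrite(path, image.data)


def write_image_truth(truth: ImageTruth, json_path, labelmap_path=None) -> None:
    """Write puncta/nuclei truth as JSON; cell masks optionally as a
    label-map TIFF (0 = background, k = cell k)."""
    payload = {
        "snr": truth.snr,
        "nuclei_centers": [list(c) for c in truth.nuclei_centers],
        "puncta": [[list(p) for p in cell] for cell in truth.puncta],
        "puncta_per_cell": [len(cell) for cell in truth.puncta],
    }
    Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
    if labelmap_path is not None:
        import tifffile

        if truth.cell_masks:
            labels = np.zeros(truth.cell_masks[0].shape, dtype=np.uint16)
            for i, mask in enumerate(truth.cell_masks, start=1):
                labels[mask] = i
            tifffile.imwrite(labelmap_path, labels)
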