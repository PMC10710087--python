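"""Generators for synthetic inputs with known ground truth.

Every stage of the pipeline can be exercised without external downloads:

* DNA sequences with purine tracts planted at known coordinates (for the
  TFO scanner);
* per-cell fluorescence populations whose means scale with circuit copy
  number (lognormal, the standard noise model for cytometry intensities);
* plate-reader dose-response grids with a known IC50 and multiplicative
  noise;
* qPCR Ct tables consistent with known relative copy numbers and
  amplification efficiency.

All generators are deterministic functions of their arguments plus an
explicit integer seed, and return the ground truth alongside the data.
A master seed is split into per-generator streams with
``numpy.random.SeedSequence.spawn`` (the documented splitting rule).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import tfo_design
from .assay_quant import four_param_logistic

__all__ = [
    "split_seed",
    "gen_sequences",
    "gen_flow_population",
    "gen_plate",
    "gen_qpcr",
    "write_fasta",
]


def split_seed(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit sub-seeds from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


# ---------------------------------------------------------------------------
# DNA sequences with planted purine tracts

def _build_run(rng: np.random.Generator, length: int, gap_count: int) -> str:
    """One purine tract of the given length with ``gap_count`` isolated
    pyrimidine interruptions (never at the ends, never adjacent)."""
    if length < 1:
        raise ValueError("run length must be >= 1")
    interior = list(range(1, length - 1))
    if gap_count > 0 and (length < 3 or gap_count > (length - 1) // 2):
        raise ValueError(f"cannot fit {gap_count} isolated gaps in a run of length {length}")
    gaps: list[int] = []
    for _ in range(10000):
        gaps = sorted(rng.choice(interior, size=gap_count, replace=False)) if gap_count else []
        if all(b - a >= 2 for a, b in zip(gaps, gaps[1:])):
            break
    else:  # pragma: no cover - rejection loop essentially always succeeds
        raise RuntimeError("failed to place gap positions")
    bases = [str(rng.choice(["A", "G"])) for _ in range(length)]
    for g in gaps:
        bases[g] = str(rng.choice(["C", "T"]))
    return "".join(bases)


def gen_sequences(
    n_seqs: int,
    length: int,
    runs_spec: Sequence[tuple[int, int]],
    seed: int,
    min_length: int = tfo_design.DEFAULT_MIN_LENGTH,
    background_purine_prob: float = 0.25,
    max_tries: int = 500,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sequences with planted maximal purine tracts and a truth table.

    Each of the ``n_seqs`` sequences carries one planted run per
    ``runs_spec`` entry ``(run_length, gap_count)``, flanked by two
    pyrimidines on each side so the planted run is maximal, at positions
    drawn without overlap.  Background bases are purine-poor, and each
    candidate sequence is rejection-checked with the scanner: it is accepted
    only when the maximal-site set of length >= ``min_length`` equals the
    planted set exactly.

    Returns ``(records, truth)`` where records are ``(seq_id, sequence)``
    pairs and truth is a BED-like frame (seq_id, start, end, length,
    gap_count).
    """
    total_planted = sum(rl + 4 for rl, _ in runs_spec)
    if total_planted > length:
        raise ValueError(
            f"planted runs (+flanks) need {total_planted} bases but length is {length}"
        )
    for run_len, gap_count in runs_spec:
        if run_len >= length:
            raise ValueError("planted run does not fit in sequence")
        if run_len < min_length:
            raise ValueError(
                f"planted run of length {run_len} is below min_length={min_length}; "
                "it could not be distinguished from background"
            )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    for i in range(n_seqs):
        seq_id = f"synth_{i:03d}"
        for _ in range(max_tries):
            seq, placed = _try_build_sequence(
                rng, length, runs_spec, background_purine_prob
            )
            if len(placed) != len(runs_spec):
                continue  # a run found no room; retry with fresh background
            found = tfo_design.find_purine_runs(seq, min_length=min_length)
            if {(s.start, s.end) for s in found} == {(a, b) for a, b, *_ in placed}:
                break
        else:
            raise RuntimeError(
                f"could not generate a clean sequence in {max_tries} tries; "
                "lower background_purine_prob or shorten the sequence"
            )
        records.append((seq_id, seq))
        for start, end, gap_count in placed:
            truth_rows.append(
                {
                    "seq_id": seq_id,
                    "start": start,
                    "end": end,
                    "length": end - start,
                    "gap_count": gap_count,
                }
            )
    truth = pd.DataFrame(
        truth_rows, columns=["seq_id", "start", "end", "length", "gap_count"]
    )
    return records, truth


def _try_build_sequence(
    rng: np.random.Generator,
    length: int,
    runs_spec: Sequence[tuple[int, int]],
    background_purine_prob: float,
) -> tuple[str, list[tuple[int, int, int]]]:
    bases = [
        str(b)
        for b in rng.choice(
            ["A", "G", "C", "T"],
            size=length,
            p=[
                background_purine_prob / 2,
                background_purine_prob / 2,
                (1 - background_purine_prob) / 2,
                (1 - background_purine_prob) / 2,
            ],
        )
    ]
    placed: list[tuple[int, int, int]] = []
    occupied: list[tuple[int, int]] = []  # [start, end) including flanks
    for run_len, gap_count in runs_spec:
        block_len = run_len + 4  # two pyrimidine flanks each side
        for _ in range(200):
            start = int(rng.integers(0, length - block_len + 1))
            block = (start, start + block_len)
            if all(block[1] <= a or block[0] >= b for a, b in occupied):
                occupied.append(block)
                run = _build_run(rng, run_len, gap_count)
                flank = [str(rng.choice(["C", "T"])) for _ in range(4)]
                bases[start : start + 2] = flank[:2]
                bases[start + 2 : start + 2 + run_len] = list(run)
                bases[start + 2 + run_len : start + block_len] = flank[2:]
                placed.append((start + 2, start + 2 + run_len, gap_count))
                break
        else:
            # no room found; caller will retry with a fresh background
            break
    placed.sort()
    return "".join(bases), placed


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Plain two-section FASTA writer with fixed line width (byte-stable)."""
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# flow-cytometry-like fluorescence populations

def gen_flow_population(
    mean: float, cv: float, n_events: int, seed: int
) -> np.ndarray:
    """Lognormal per-event fluorescence with the requested *arithmetic*
    mean and coefficient of variation.

    Moment matching: ``sigma^2 = ln(1 + cv^2)``,
    ``mu = ln(mean) - sigma^2 / 2``.
    """
    if mean <= 0 or cv <= 0:
        raise ValueError("mean and cv must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_events)


# ---------------------------------------------------------------------------
# dose-response plates

def gen_plate(
    dose_grid: Sequence[float],
    ic50: float,
    hill: float,
    top: float,
    bottom: float,
    noise_sd: float,
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Percent-growth plate: 4PL(dose) * (1 + eps), eps ~ N(0, noise_sd),
    truncated at zero.  Columns: dose, replicate, percent_growth."""
    doses = np.asarray(dose_grid, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for dose in doses:
        signal = float(four_param_logistic(np.array([dose]), bottom, top, ic50, hill)[0])
        for rep in range(1, replicates + 1):
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append(
                {
                    "dose": dose,
                    "replicate": rep,
                    "percent_growth": max(0.0, signal * (1.0 + eps)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR Ct tables

def gen_qpcr(
    copy_ratios: Mapping[str, Mapping[str, float]],
    efficiency: float = 2.0,
    ct_noise_sd: float = 0.0,
    reps: int = 3,
    seed: int = 0,
    ct_base: float = 20.0,
    reference_gene: str = "Vinculin",
) -> pd.DataFrame:
    """Tidy Ct table from known per-sample/gene copy ratios.

    ``Ct = ct_base - log_E(ratio) + N(0, ct_noise_sd)``; the reference gene
    is emitted for every sample with ratio fixed at 1.  Columns: sample,
    gene, replicate, ct, efficiency.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must lie in (1, 2]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for sample, genes in copy_ratios.items():
        all_genes = dict(genes)
        all_genes.setdefault(reference_gene, 1.0)
        for gene, ratio in all_genes.items():
            if ratio <= 0:
                raise ValueError(f"copy ratio must be > 0 ({sample}/{gene})")
            ct_true = ct_base - np.log(ratio) / np.log(efficiency)
            for rep in range(1, reps + 1):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "replicate": rep,
                        "ct": ct_true + noise,
                        "efficiency": efficiency,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundled truth output

def dump_truth(truth: Mapping, path: str | Path) -> None:
    """Write a ground-truth JSON (sorted keys; byte-stable)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
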