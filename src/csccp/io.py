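"""File formats and the batch elucidation pipeline.

Scaffold JSON schema (one file per scaffold, possibly many configurations)::

    {"scaffold_id": "...",
     "configurations": [
       {"positions": [
         {"sidechains": [{"id": "...", "weight": 60.05, "probability": 0.4},
                          ...]},
         ...]},
       ...]}

The reader pads the ``n x h`` weight/probability matrices with zeros up to
``h = max(K)`` columns.  Peak lists are CSV with header
``peak_id,mass_min,mass_max`` or the dialect ``peak_id,mass,tolerance``
(window = mass +/- tolerance).  Results are written as TSV with one row per
returned candidate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import CsccpError, MassPeak, ScaffoldConfiguration
from .resources import DEFAULT_DEVICE, DeviceProfile, classify_feasibility
from .solver import solve_csccp

__all__ = [
    "RunConfig",
    "read_scaffold_json",
    "write_scaffold_json",
    "read_peaks_csv",
    "write_results_tsv",
    "write_feasibility_csv",
    "run_batch",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "scaffold_id",
    "config_index",
    "peak_id",
    "rank",
    "probability",
    "total_sidechain_mass",
    "sidechain_ids",
]


@dataclass(frozen=True)
class RunConfig:
    """Run parameters; defaults R=3, D=5, w_max cap 500 Da."""

    rank: int = 3
    digits: int = 5
    w_max: float = 500.0
    device: DeviceProfile = field(default_factory=lambda: DEFAULT_DEVICE)
    traceback: str = "raw"  # or "packed"
    force: bool = False
    seed: int = 0


def read_scaffold_json(path: str | Path) -> list[ScaffoldConfiguration]:
    """Parse one scaffold file into its configurations."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise CsccpError(f"{path}: malformed JSON ({exc})") from exc
    try:
        scaffold_id = doc["scaffold_id"]
        out = []
        for idx, conf in enumerate(doc["configurations"]):
            positions = conf["positions"]
            K = [len(p["sidechains"]) for p in positions]
            if not K or min(K) < 1:
                raise CsccpError(
                    f"{path}: configuration {idx} has a position without sidechains"
                )
            h = max(K)
            n = len(K)
            W = np.zeros((n, h))
            P = np.zeros((n, h))
            labels: list[list[str]] = []
            for s, p in enumerate(positions):
                lab = []
                for j, sc in enumerate(p["sidechains"]):
                    W[s, j] = float(sc["weight"])
                    P[s, j] = float(sc["probability"])
                    lab.append(str(sc.get("id", f"s{s}j{j}")))
                labels.append(lab)
            out.append(
                ScaffoldConfiguration(
                    scaffold_id=scaffold_id,
                    config_index=idx,
                    K=np.array(K),
                    W=W,
                    P=P,
                    sidechain_labels=labels,
                )
            )
        return out
    except (KeyError, TypeError) as exc:
        raise CsccpError(f"{path}: missing or malformed field ({exc!r})") from exc


def write_scaffold_json(path: str | Path, configurations: Sequence[ScaffoldConfiguration]) -> None:
    """Write configurations (sharing one scaffold_id) to the JSON schema."""
    if not configurations:
        raise ValueError("nothing to write")
    scaffold_id = configurations[0].scaffold_id
    doc = {"scaffold_id": scaffold_id, "configurations": []}
    for cfg in configurations:
        positions = []
        for s in range(cfg.n):
            sidechains = []
            for j in range(int(cfg.K[s])):
                sidechains.append(
                    {
                        "id": cfg.sidechain_labels[s][j]
                        if cfg.sidechain_labels
                        else f"s{s}j{j}",
                        "weight": float(cfg.W[s, j]),
                        "probability": float(cfg.P[s, j]),
                    }
                )
            positions.append({"sidechains": sidechains})
        doc["configurations"].append({"positions": positions})
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_peaks_csv(path: str | Path, digits: int) -> list[tuple[str, MassPeak]]:
    """Parse a peak list; supports min/max and mass +/- tolerance dialects."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise CsccpError(f"{path}: unreadable CSV ({exc})") from exc
    cols = set(df.columns)
    out: list[tuple[str, MassPeak]] = []
    if {"peak_id", "mass_min", "mass_max"} <= cols:
        for i, row in df.iterrows():
            out.append(
                (
                    str(row["peak_id"]),
                    MassPeak(float(row["mass_min"]), float(row["mass_max"]), digits),
                )
            )
    elif {"peak_id", "mass", "tolerance"} <= cols:
        for i, row in df.iterrows():
            m, t = float(row["mass"]), float(row["tolerance"])
            if t < 0:
                raise CsccpError(f"{path}: row {i}: negative tolerance {t}")
            out.append((str(row["peak_id"]), MassPeak(m - t, m + t, digits)))
    else:
        raise CsccpError(
            f"{path}: expected header peak_id,mass_min,mass_max or "
            f"peak_id,mass,tolerance; got {sorted(cols)}"
        )
    return out


def write_results_tsv(results: pd.DataFrame, path: str | Path) -> None:
    """Write the candidate table as UTF-8 TSV with a header."""
    results.to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_feasibility_csv(report: pd.DataFrame, path: str | Path) -> None:
    """Write a feasibility survey (one row per D) as UTF-8 CSV."""
    report.to_csv(path, encoding="utf-8")


def run_batch(
    scaffold_db: Iterable[ScaffoldConfiguration],
    peaks: Sequence[tuple[str, MassPeak]],
    config: RunConfig,
) -> pd.DataFrame:
    """Solve every (peak, configuration) pair; merged per-peak ranking.

    Each configuration is an independent problem contributing up to R
    candidates, so a scaffold with N_r configurations yields up to
    ``R * N_r`` rows per peak.  Within a peak, rows are ordered by
    probability descending, ties by scaffold_id, config_index, then rank
    ascending — the row order is the merged ranking.  Configurations whose
    window exceeds the w_max cap or that the device model refuses are
    logged and skipped (unless ``config.force``).
    """
    cfgs = list(scaffold_db)
    rows: list[dict] = []
    for peak_id, peak in peaks:
        if peak.w_max > config.w_max:
            logger.warning(
                "peak %s: w_max %.4f exceeds cap %.1f Da; skipped",
                peak_id, peak.w_max, config.w_max,
            )
            continue
        peak_d = MassPeak(peak.w_min, peak.w_max, config.digits)
        for cfg in cfgs:
            verdict = classify_feasibility(
                cfg, config.rank, config.digits, peak_d.w_max, config.device
            )
            if not verdict.feasible and not config.force:
                logger.warning(
                    "peak %s scaffold %s[%d]: skipped (%s)",
                    peak_id, cfg.scaffold_id, cfg.config_index, verdict.category,
                )
                continue
            candidates = solve_csccp(
                cfg, peak_d, config.rank,
                traceback=config.traceback, force=True,
            )
            for cand in candidates:
                rows.append(
                    {
                        "scaffold_id": cfg.scaffold_id,
                        "config_index": cfg.config_index,
                        "peak_id": peak_id,
                        "rank": cand.rank,
                        "probability": cand.probability,
                        "total_sidechain_mass": format(
                            cand.mass_da(config.digits), f".{config.digits}f"
                        ),
                        "sidechain_ids": ";".join(cfg.labels_for(cand.selection)),
                    }
                )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(df):
        df = (
            df.sort_values(
                ["peak_id", "probability", "scaffold_id", "config_index", "rank"],
                ascending=[True, False, True, True, True],
                kind="mergesort",
            )
            .reset_index(drop=True)
        )
    return df
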