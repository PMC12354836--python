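"""Editing-frequency estimation from Sanger chromatogram peak amplitudes.

At the edited position the estimator is the two-channel peak-amplitude
ratio edited/(edited+primary): for a C-to-U site read in transcript
orientation, T/(T+C). Reverse-orientation traces are handled by
complementing both bases before channel lookup (C-to-U then reads as
A/(A+G)). Only the two relevant channels enter the denominator; no
baseline correction is applied by default.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from editscan.model import COMPLEMENT, AmplitudeWindow


def editing_fraction(
    w: AmplitudeWindow,
    primary: str,
    edited: str,
    median_baseline: bool = False,
) -> float:
    """Peak-amplitude editing fraction at the window's target position.

    ``primary``/``edited`` are given on the transcript strand; for a
    reverse-orientation window both are complemented before lookup.
    With ``median_baseline`` each channel's window median is subtracted
    first (clipped at zero).
    """
    if primary == edited:
        raise ValueError("primary and edited base must differ")
    if w.orientation == "reverse":
        primary, edited = COMPLEMENT[primary], COMPLEMENT[edited]
    amp_p = np.asarray(w.amp[primary], dtype=float)
    amp_e = np.asarray(w.amp[edited], dtype=float)
    if median_baseline:
        amp_p = np.clip(amp_p - np.median(amp_p), 0.0, None)
        amp_e = np.clip(amp_e - np.median(amp_e), 0.0, None)
    p = amp_p[w.target_index]
    e = amp_e[w.target_index]
    if p + e == 0:
        raise ValueError("no signal: both channel amplitudes are zero at the target")
    return float(e / (p + e))


def read_amplitude_tsv(
    path: str | Path, target_index: int, orientation: str = "forward"
) -> AmplitudeWindow:
    """Load a per-basecall amplitude table (columns: position, A, C, G, T)."""
    df = pd.read_csv(path, sep="\t")
    required = {"position", "A", "C", "G", "T"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"amplitude table missing columns: {sorted(missing)}")
    return AmplitudeWindow(
        positions=[int(p) for p in df["position"]],
        amp={b: [float(v) for v in df[b]] for b in "ACGT"},
        target_index=target_index,
        orientation=orientation,
    )


def write_amplitude_tsv(w: AmplitudeWindow, path: str | Path) -> None:
    pd.DataFrame(
        {
            "position": w.positions,
            **{b: w.amp[b] for b in "ACGT"},
        }
    ).to_csv(path, sep="\t", index=False)


def read_ab1(
    path: str | Path, query: str, orientation: str = "forward"
) -> AmplitudeWindow:
    """Extract per-basecall peak amplitudes from an ABIF trace file and
    centre the window on the middle of a query-sequence match.

    Uses the analysed trace channels (DATA9-12, base order from FWO_1)
    sampled at the basecall peak locations (PLOC2/PLOC1).
    """
    from Bio import SeqIO

    rec = SeqIO.read(str(path), "abi")
    raw = rec.annotations["abif_raw"]
    order_raw = raw.get("FWO_1", b"GATC")
    order = order_raw.decode() if isinstance(order_raw, bytes) else str(order_raw)
    ploc = raw.get("PLOC2", raw.get("PLOC1"))
    if ploc is None:
        raise ValueError("ABIF file lacks basecall peak locations (PLOC)")
    traces = {
        base: raw[f"DATA{9 + i}"] for i, base in enumerate(order)
    }
    basecalls = str(rec.seq)
    idx = basecalls.find(query.upper())
    if idx < 0:
        best = _best_partial_match(basecalls, query.upper())
        raise ValueError(f"query not found in basecalls; best partial match at {best}")
    positions = list(range(idx, idx + len(query)))
    amp = {
        base: [float(traces[base][ploc[p]]) for p in positions] for base in "ACGT"
    }
    return AmplitudeWindow(
        positions=positions,
        amp=amp,
        target_index=len(query) // 2,
        orientation=orientation,
    )


def _best_partial_match(haystack: str, needle: str) -> Optional[int]:
    best_i, best_score = None, -1
    for i in range(max(1, len(haystack) - len(needle) + 1)):
        window = haystack[i : i + len(needle)]
        score = sum(a == b for a, b in zip(window, needle))
        if score > best_score:
            best_i, best_score = i, score
    return best_i
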