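"""Drift correction and concentration normalization for ICP-MS runs.

Instrument sensitivity drifts over an analytical run. A pooled liquid
reference standard is measured at the run start and at fixed intervals;
linear interpolation between successive reference measurements yields a
theoretical reference signal at every record position, and each record is
rescaled by simple proportion to the first reference:

    corrected = raw * ref_first / ref_theoretical(position)

Runs acquired at different times are bridged by applying the per-run
correction and then rescaling each run so that its first reference matches
the first reference of the first run. Final concentrations subtract blank
signal (floored at zero), multiply by the dilution factor and normalize to
the sample dry weight.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .containers import ElementalProfile, ElementalRun

__all__ = ["correct_drift", "bridge_runs", "blank_means", "finalize_concentrations"]

log = logging.getLogger(__name__)


def _reference_rows(run: ElementalRun) -> np.ndarray:
    idx = np.flatnonzero((run.meta["record_type"] == "reference").to_numpy())
    if idx.size == 0:
        raise ValueError("run has no reference records")
    return idx


def correct_drift(run: ElementalRun) -> ElementalRun:
    """Remove multiplicative drift using the run's reference records.

    Between references the theoretical reference is linearly interpolated on
    record position; before the first / after the last reference the nearest
    reference value is carried (constant extrapolation). Reference records
    themselves map exactly onto the first reference value.
    """
    ref_idx = _reference_rows(run)
    positions = run.meta["position"].to_numpy(float)
    ref_pos = positions[ref_idx]
    inten = run.intensities.to_numpy(float)
    ref_vals = inten[ref_idx, :]
    if np.isnan(ref_vals).any():
        raise ValueError("element missing from a reference record")
    corrected = np.empty_like(inten)
    for j in range(inten.shape[1]):
        theoretical = np.interp(positions, ref_pos, ref_vals[:, j])
        if (theoretical <= 0).any():
            raise ValueError(
                f"non-positive theoretical reference for element "
                f"{run.intensities.columns[j]!r}"
            )
        corrected[:, j] = inten[:, j] * ref_vals[0, j] / theoretical
    out = ElementalRun(
        meta=run.meta.copy(),
        intensities=pd.DataFrame(
            corrected, columns=run.intensities.columns, index=run.intensities.index
        ),
    )
    return out


def bridge_runs(runs: list[ElementalRun]) -> ElementalRun:
    """Connect drift-corrected runs onto the first run's reference scale.

    Runs are ordered canonically by ``run_id``; each run is drift-corrected,
    then rescaled so its first reference equals the first run's first
    reference, and the record sequences are concatenated with strictly
    increasing positions.
    """
    if not runs:
        raise ValueError("no runs given")
    element_sets = [tuple(sorted(r.elements)) for r in runs]
    if len(set(element_sets)) != 1:
        raise ValueError("runs do not share a common element set")
    elements = runs[0].elements
    ordered = sorted(runs, key=lambda r: str(r.meta["run_id"].iloc[0]))
    corrected = [correct_drift(r) for r in ordered]

    def first_ref(run: ElementalRun) -> np.ndarray:
        i = _reference_rows(run)[0]
        return run.intensities[elements].to_numpy(float)[i]

    anchor = first_ref(corrected[0])
    metas, intens = [], []
    offset = 0.0
    for run in corrected:
        scale = anchor / first_ref(run)
        vals = run.intensities[elements].to_numpy(float) * scale
        meta = run.meta.copy()
        meta["position"] = meta["position"].to_numpy(float) + offset
        offset = float(meta["position"].iloc[-1]) + 1.0
        metas.append(meta)
        intens.append(pd.DataFrame(vals, columns=elements))
    return ElementalRun(
        meta=pd.concat(metas, ignore_index=True),
        intensities=pd.concat(intens, ignore_index=True),
    )


def blank_means(run: ElementalRun) -> pd.Series:
    """Mean intensity of the run's blank records, per element."""
    mask = (run.meta["record_type"] == "blank").to_numpy()
    if not mask.any():
        raise ValueError("run has no blank records")
    return run.intensities.loc[mask].mean(axis=0)


def finalize_concentrations(
    run: ElementalRun, blanks: Mapping[str, float] | pd.Series | None = None
) -> ElementalProfile:
    """Blank-subtract, dilution-scale and dry-weight-normalize sample records.

    conc = max(raw - blank, 0) * dilution_factor / dry_weight. Reference and
    blank records are excluded from the output. Negative blank-subtracted
    values are floored at zero and logged.
    """
    if blanks is None:
        blanks = blank_means(run)
    blanks = pd.Series(blanks, dtype=float)
    missing = [e for e in run.elements if e not in blanks.index]
    if missing:
        raise ValueError(f"blank values missing for elements: {missing}")
    mask = (run.meta["record_type"] == "sample").to_numpy()
    meta = run.meta.loc[mask]
    dw = meta["dry_weight_g"].to_numpy(float)
    bad = dw <= 0
    if bad.any():
        raise ValueError(
            f"non-positive dry weight for samples: {meta['sample_id'].to_numpy()[bad].tolist()}"
        )
    raw = run.intensities.loc[mask, run.elements].to_numpy(float)
    sub = raw - blanks[run.elements].to_numpy(float)[None, :]
    n_floored = int((sub < 0).sum())
    if n_floored:
        log.warning("floored %d negative blank-subtracted values at 0", n_floored)
    sub = np.maximum(sub, 0.0)
    conc = sub * meta["dilution_factor"].to_numpy(float)[:, None] / dw[:, None]
    frame = pd.DataFrame(conc, index=meta["sample_id"].to_numpy(), columns=run.elements)
    frame.index.name = "sample_id"
    return ElementalProfile(concentrations=frame)
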