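"""Ligand-binding event detection and classification.

Binding to a pocket is declared from anchor-atom distances: a contact
requires each of the (two, by default) anchor atoms of the site to be
within the cutoff of some ligand heavy atom.  A stricter single-anchor +
ligand-RMSD criterion is available for pockets with a known crystallographic
pose.  Per-trajectory contact series are debounced into bound intervals and
classified as none / transient / stable; stable-complex windows are found by
windowed ligand RMSF; per-trajectory activation barriers are read off the
smoothed potential-energy trace between first pocket contact and stable
binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class SiteDefinition:
    """A binding pocket defined by anchor atoms and a contact cutoff (Å-free:
    the cutoff is in the same length unit as the coordinates, nm internally,
    default 0.5 nm = 5 Å)."""

    name: str
    anchors: tuple = ()               # ((residue, atom), ...) references
    cutoff: float = 0.5               # nm

    def __post_init__(self) -> None:
        if len(self.anchors) < 1:
            raise ValueError("site needs at least one anchor atom")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class BindingRecord:
    """Outcome of one ligand copy in one trajectory."""

    trajectory_id: str
    ligand_id: int
    site: str
    first_contact: Optional[float] = None        # ns
    intervals: list = field(default_factory=list)  # [(start, end) ns]
    outcome: str = "none"                        # none | transient | stable
    barrier: Optional[float] = None              # kcal/mol


def _min_image(d: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    if box is not None:
        d = d - box * np.round(d / box)
    return d


def site_contact(anchor_coords: np.ndarray, ligand_coords: np.ndarray,
                 cutoff: float = 0.5, box: Optional[np.ndarray] = None,
                 mode: str = "distinct_anchors") -> bool:
    """Contact test: "at least two distances below cutoff".

    ``distinct_anchors`` (default): every anchor atom must lie within the
    cutoff of some ligand heavy atom — the natural two-point
    pocket-engagement reading for two-anchor sites.  ``any_two_pairs``:
    any two (anchor, ligand-atom) pairs below the cutoff, possibly sharing
    an anchor.  Distances are minimum-image when a box is given; the
    comparison is strict (< cutoff).
    """
    anchor_coords = np.atleast_2d(anchor_coords)
    ligand_coords = np.atleast_2d(ligand_coords)
    d = anchor_coords[:, None, :] - ligand_coords[None, :, :]
    d = _min_image(d, box)
    dist = np.sqrt(np.sum(d * d, axis=2))
    if mode == "distinct_anchors":
        return bool(np.all(np.min(dist, axis=1) < cutoff))
    if mode == "any_two_pairs":
        return int(np.count_nonzero(dist < cutoff)) >= 2
    raise ValueError(f"unknown contact mode {mode!r}")


def ligand_rmsd(pose: np.ndarray, reference: np.ndarray) -> float:
    """RMSD over ligand heavy atoms, no re-fitting; symmetric in arguments."""
    pose = np.asarray(pose, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if pose.shape != reference.shape:
        raise ValueError(f"atom count mismatch: {pose.shape} vs {reference.shape}")
    return float(np.sqrt(np.mean(np.sum((pose - reference) ** 2, axis=-1))))


def strict_pocket_binding(anchor_coord: np.ndarray, ligand_coords: np.ndarray,
                          crystal_pose: np.ndarray, cutoff: float = 0.5,
                          rmsd_cutoff: float = 0.9,
                          box: Optional[np.ndarray] = None) -> bool:
    """Strict two-condition pocket-entry criterion.

    True iff (1) the single anchor atom is within ``cutoff`` (inclusive, ≤)
    of any ligand heavy atom and (2) the ligand RMSD from the
    crystallographic pose (pre-aligned to the protein frame) is below
    ``rmsd_cutoff`` (exclusive, <).  Defaults 0.5 / 0.9 nm = 5 / 9 Å.
    """
    anchor_coord = np.asarray(anchor_coord, dtype=float).reshape(1, 3)
    d = _min_image(anchor_coord - np.atleast_2d(ligand_coords), box)
    dist_ok = bool(np.min(np.sqrt(np.sum(d * d, axis=1))) <= cutoff)
    rmsd_ok = ligand_rmsd(ligand_coords, crystal_pose) < rmsd_cutoff
    return dist_ok and rmsd_ok


def contact_intervals(contact: np.ndarray, times_ns: np.ndarray,
                      debounce_ns: float = 0.1) -> list[tuple[float, float]]:
    """Merge a boolean contact series into debounced intervals.

    Gaps and blips shorter than ``debounce_ns`` are smoothed away, which
    suppresses single-frame flicker at the cutoff boundary.
    """
    contact = np.asarray(contact, dtype=bool)
    times_ns = np.asarray(times_ns, dtype=float)
    if len(contact) != len(times_ns):
        raise ValueError("contact and time series must be congruent")
    # maximal contact runs -> (start, end) on contact-sample times
    raw: list[list[float]] = []
    for i, c in enumerate(contact):
        if c:
            if raw and len(raw[-1]) == 1:
                continue
            raw.append([times_ns[i]])
        elif raw and len(raw[-1]) == 1:
            raw[-1].append(times_ns[i - 1])
    if raw and len(raw[-1]) == 1:
        raw[-1].append(times_ns[-1])
    # merge intervals separated by a gap at or below the debounce window
    # (a single-frame dropout at frame spacing dt shows as a gap of 2*dt)
    merged: list[list[float]] = []
    for s, e in raw:
        if merged and s - merged[-1][1] <= debounce_ns:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    # drop blips shorter than the debounce window unless they reach the end
    return [(s, e) for s, e in merged
            if e - s >= debounce_ns or e == times_ns[-1]]


def classify_trajectory(contact_series: np.ndarray, times_ns: np.ndarray,
                        trajectory_id: str = "traj", ligand_id: int = 0,
                        site: str = "site", debounce_ns: float = 0.1,
                        min_stable_ns: float = 10.0) -> BindingRecord:
    """Classify one ligand copy from its per-frame contact series.

    ``none``: no bound interval; ``transient``: every interval ends before
    the trajectory end; ``stable``: the final interval persists to the end
    of the trajectory and lasts at least ``min_stable_ns``.
    """
    rec = BindingRecord(trajectory_id=trajectory_id, ligand_id=ligand_id, site=site)
    iv = contact_intervals(contact_series, times_ns, debounce_ns)
    rec.intervals = iv
    if not iv:
        return rec
    rec.first_contact = iv[0][0]
    end = float(np.asarray(times_ns)[-1])
    last_start, last_end = iv[-1]
    if last_end >= end - 1e-9 and (last_end - last_start) >= min_stable_ns:
        rec.outcome = "stable"
    else:
        rec.outcome = "transient"
    return rec


def rmsf_stable_windows(ligand_positions: np.ndarray, times_ns: np.ndarray,
                        window_ns: float = 10.0, rmsf_cutoff: float = 0.3,
                        protein_positions: Optional[np.ndarray] = None
                        ) -> list[dict]:
    """Stable-complex windows by windowed ligand RMSF.

    The trajectory (already protein-superposed) is cut into consecutive
    non-overlapping windows of ``window_ns``.  Within each window the ligand
    RMSF about the window-mean coordinates is computed; windows with
    RMSF < ``rmsf_cutoff`` (default 0.3 nm = 3 Å) are returned with the mean
    ligand (and protein, if supplied) coordinates.
    """
    ligand_positions = np.asarray(ligand_positions, dtype=float)  # (T, n, 3)
    times_ns = np.asarray(times_ns, dtype=float)
    t0 = times_ns[0]
    span = times_ns[-1] - t0
    # a trailing window short of full coverage only by the frame spacing
    # still counts (a 100-ns run sampled to 99.5 ns has ten 10-ns windows)
    n_windows = int(np.ceil(span / window_ns - 1e-9))
    out = []
    for w in range(n_windows):
        lo, hi = t0 + w * window_ns, t0 + (w + 1) * window_ns
        sel = (times_ns >= lo) & (times_ns < hi) if w < n_windows - 1 else \
              (times_ns >= lo) & (times_ns <= hi + 1e-9)
        if np.count_nonzero(sel) < 2:
            continue
        coords = ligand_positions[sel]
        mean = coords.mean(axis=0)
        rmsf = float(np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2))))
        if rmsf < rmsf_cutoff:
            entry = {"window": (lo, hi), "rmsf": rmsf, "ligand_mean": mean}
            if protein_positions is not None:
                entry["protein_mean"] = np.asarray(protein_positions)[sel].mean(axis=0)
            out.append(entry)
    return out


def extract_barrier(energy: np.ndarray, times: np.ndarray,
                    unbound_window: tuple[float, float],
                    contact_time: float, binding_time: float,
                    smoothing: int = 50) -> Optional[float]:
    """Activation barrier from a potential-energy trace, kcal/mol.

    The trace is smoothed by a centered running mean of ``smoothing``
    samples; the barrier is the smoothed maximum over the transition
    interval (first pocket contact → onset of stable binding) minus the
    smoothed-trace mean over the unbound window.  Returns None when the
    transition interval contains no samples.  Invariant under adding a
    constant to the whole trace.
    """
    energy = np.asarray(energy, dtype=float)
    times = np.asarray(times, dtype=float)
    if smoothing > 1:
        kernel = np.ones(min(smoothing, len(energy))) / min(smoothing, len(energy))
        smooth = np.convolve(energy, kernel, mode="same")
        # undo edge attenuation of the boxcar
        norm = np.convolve(np.ones_like(energy), kernel, mode="same")
        smooth = smooth / norm
    else:
        smooth = energy
    ub = (times >= unbound_window[0]) & (times <= unbound_window[1])
    if not np.any(ub):
        raise ValueError("unbound window contains no samples")
    baseline = float(np.mean(smooth[ub]))
    tr = (times >= contact_time) & (times <= binding_time)
    if not np.any(tr):
        return None
    return float(np.max(smooth[tr]) - baseline)
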