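"""Error metrics for validating alignment against ground truth."""

from __future__ import annotations

import numpy as np

from .tomosim import RigidParams, GroundTruthRecord

__all__ = ["angular_distance", "shift_distance", "alignment_errors"]


def angular_distance(r1: RigidParams, r2: RigidParams) -> float:
    """Geodesic distance (deg) between two rotations."""
    R = r1.matrix() @ r2.matrix().T
    cos = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def shift_distance(r1: RigidParams, r2: RigidParams) -> float:
    """Euclidean distance (voxels) between two shift vectors."""
    return float(np.linalg.norm(np.asarray(r1.shift) - np.asarray(r2.shift)))


def alignment_errors(table, records: list[GroundTruthRecord],
                     mode_numbers: tuple[int, ...]):
    """Per-subtomogram absolute errors of an alignment table vs ground truth.

    ``table`` is the DataFrame from :func:`flexitomo.align.align_dataset`;
    ground-truth amplitudes default to 0 for modes the generator did not use.
    Returns a DataFrame with columns ``err_a<mode>``, ``angular``, ``shift``.
    """
    import pandas as pd

    rows = []
    for _, row in table.iterrows():
        rec = records[int(row["index"])]
        truth = dict(zip(rec.mode_numbers, rec.amplitudes))
        est_rigid = RigidParams((row["rot"], row["tilt"], row["psi"]),
                                (row["x"], row["y"], row["z"]))
        out = {"index": int(row["index"]), "label": rec.label}
        for num in mode_numbers:
            out[f"err_a{num}"] = abs(row[f"a{num}"] - truth.get(num, 0.0))
        out["angular"] = angular_distance(est_rigid, rec.rigid)
        out["shift"] = shift_distance(est_rigid, rec.rigid)
        rows.append(out)
    return pd.DataFrame(rows)
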