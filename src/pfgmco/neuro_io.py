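"""NIfTI volume and federation-manifest I/O, plus cross-validation folds.

A federation is described by a CSV manifest with one row per subject:
``subject_id, path_smri, path_alff, path_reho, label, site_id, client_id,
fold``.  Volumes are NIfTI-1 files consumed as stored — shape mismatches are
errors, never silently resampled, because spatial preprocessing happens
upstream of this package.  Voxel coordinates are 0-based throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import ClientData

__all__ = [
    "REQUIRED_COLUMNS",
    "FederationManifest",
    "ManifestError",
    "load_manifest",
    "load_volume",
    "save_volume",
    "make_folds",
    "write_manifest",
    "load_cohort_roster",
    "cohort_manifest_skeleton",
]

REQUIRED_COLUMNS = ("subject_id", "path_smri", "path_alff", "path_reho",
                    "label", "site_id", "client_id")
PATH_COLUMNS = ("path_smri", "path_alff", "path_reho")


class ManifestError(ValueError):
    """Raised with the full list of manifest violations, not just the first."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid manifest:\n  " + "\n  ".join(violations))


@dataclass
class FederationManifest:
    """Validated subject table; ``rows`` is a pandas DataFrame."""

    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)

    def client_ids(self) -> list[str]:
        return sorted(self.rows["client_id"].unique())

    def client_rows(self, client_id: str) -> pd.DataFrame:
        return self.rows[self.rows["client_id"] == client_id]


def _validate(df: pd.DataFrame, check_paths: bool) -> list[str]:
    violations = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing required column {c!r}" for c in missing]
    dup = df["subject_id"][df["subject_id"].duplicated()]
    violations += [f"duplicate subject_id {s!r}" for s in dup.unique()]
    bad = df.loc[~df["label"].isin([0, 1]), "subject_id"]
    violations += [f"label outside {{0,1}} for subject {s!r}" for s in bad]
    if "fold" in df.columns:
        badf = df.loc[df["fold"] < -1, "subject_id"]
        violations += [f"negative fold for subject {s!r}" for s in badf]
    if check_paths:
        for col in PATH_COLUMNS:
            for s, p in zip(df["subject_id"], df[col]):
                if not Path(p).exists():
                    violations.append(
                        f"{col} for subject {s!r} does not exist: {p}")
    return violations


def load_manifest(path: str | Path, check_paths: bool = True
                  ) -> FederationManifest:
    """Load and validate a manifest CSV; reports *all* violations at once."""
    df = pd.read_csv(path)
    violations = _validate(df, check_paths=check_paths)
    if violations:
        raise ManifestError(violations)
    if "fold" not in df.columns:
        df = df.assign(fold=-1)
    return FederationManifest(df.reset_index(drop=True))


def load_volume(path: str | Path) -> np.ndarray:
    """Read a 3D NIfTI volume in its native voxel order."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    return data.astype(np.float64)


def save_volume(data: np.ndarray, path: str | Path,
                affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D")
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64),
                          np.eye(4) if affine is None else affine)
    nib.save(img, str(path))
    return path


def make_folds(manifest: FederationManifest, k: int = 5,
               seed: int = 0) -> FederationManifest:
    """Assign cross-validation folds, stratified by label within each client.

    Fold sizes differ by at most one within each client-class stratum.  A
    client holding fewer than ``k`` samples of some class degrades, with a
    warning, to non-stratified assignment within that client.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    df = manifest.rows.copy()
    fold = np.full(len(df), -1, dtype=int)
    for cid in sorted(df["client_id"].unique()):
        cmask = (df["client_id"] == cid).to_numpy()
        class_sizes = df.loc[cmask, "label"].value_counts()
        if (class_sizes < k).any():
            warnings.warn(
                f"client {cid!r} has a class with fewer than {k} samples; "
                "using non-stratified folds for this client", stacklevel=2)
            idx = np.flatnonzero(cmask)
            rng.shuffle(idx)
            fold[idx] = np.arange(len(idx)) % k
            continue
        for label in (0, 1):
            idx = np.flatnonzero(cmask & (df["label"] == label).to_numpy())
            rng.shuffle(idx)
            fold[idx] = np.arange(len(idx)) % k
    df["fold"] = fold
    return FederationManifest(df)


def write_manifest(datasets: list[ClientData], directory: str | Path,
                   k_folds: int = 5, seed: int = 0) -> Path:
    """Write one NIfTI file per volume plus a manifest CSV with CV folds."""
    if not datasets:
        raise ValueError("datasets must be nonempty")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for client in datasets:
        cdir = directory / client.client_id
        cdir.mkdir(exist_ok=True)
        for s in client.samples:
            paths = {}
            for mod, vol in (("smri", s.x_s), ("alff", s.x_a), ("reho", s.x_r)):
                p = cdir / f"{s.subject_id}_{mod}.nii.gz"
                save_volume(vol, p)
                paths[f"path_{mod}"] = str(p)
            records.append({"subject_id": s.subject_id, **paths,
                            "label": s.y, "site_id": s.site_id,
                            "client_id": s.client_id})
    manifest = FederationManifest(pd.DataFrame.from_records(records))
    manifest = make_folds(manifest, k=k_folds, seed=seed)
    out = directory / "manifest.csv"
    manifest.rows.to_csv(out, index=False)
    return out


# ---------------------------------------------------------------------------
# Packaged multisite cohort roster (per-client site lists and class counts)
# ---------------------------------------------------------------------------

def load_cohort_roster() -> pd.DataFrame:
    """Per-client roster of the 23-site, 2293-subject MDD cohort.

    Columns: client_id, site_indices (';'-joined), n_nc, n_mdd.  The subject-
    level table is reconstructed programmatically by
    `cohort_manifest_skeleton`.
    """
    with resources.files("pfgmco.data").joinpath("mdd_cohort_clients.csv").open() as f:
        return pd.read_csv(f)


def cohort_manifest_skeleton() -> FederationManifest:
    """Expand the packaged roster into a subject-level manifest skeleton.

    Paths are synthetic placeholders (the underlying MRI data are access
    restricted and not distributed); labels and per-client totals follow the
    roster, with label 0 = control, 1 = patient.  Useful for exercising fold
    logic and for auditing cohort sizes.
    """
    roster = load_cohort_roster()
    records = []
    for _, row in roster.iterrows():
        site = row["site_indices"].split(";")[0]
        for label, count in ((0, row["n_nc"]), (1, row["n_mdd"])):
            for k in range(int(count)):
                sid = f"{row['client_id']}-{'nc' if label == 0 else 'mdd'}-{k:04d}"
                records.append({
                    "subject_id": sid,
                    "path_smri": f"<restricted>/{sid}_smri.nii.gz",
                    "path_alff": f"<restricted>/{sid}_alff.nii.gz",
                    "path_reho": f"<restricted>/{sid}_reho.nii.gz",
                    "label": label, "site_id": site,
                    "client_id": row["client_id"]})
    df = pd.DataFrame.from_records(records)
    violations = _validate(df, check_paths=False)
    if violations:  # pragma: no cover - roster is packaged
        raise ManifestError(violations)
    return FederationManifest(df.assign(fold=-1))
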