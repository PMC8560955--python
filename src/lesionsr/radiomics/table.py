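"""Feature tables across subjects, bin settings and ROI versions.

A :class:`FeatureTable` is a tidy long pandas DataFrame with columns
``subject, roi_version, n_bins, feature, value`` (plus ``na_reason`` for
cells that could not be computed), rectangular over the requested axes —
missing cells are explicit, never silent.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, extract_features

__all__ = ["FeatureTable", "build_table", "DEFAULT_BINS"]

DEFAULT_BINS = (8, 16, 32, 64, 128, 256)

COLUMNS = ["subject", "roi_version", "n_bins", "feature", "value", "na_reason"]


class FeatureTable:
    """Tidy long table of radiomic feature values with explicit NA cells."""

    def __init__(self, frame: pd.DataFrame):
        missing = set(COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)

    @property
    def subjects(self) -> list:
        return sorted(self.frame["subject"].unique().tolist())

    @property
    def bins(self) -> list[int]:
        return sorted(int(b) for b in self.frame["n_bins"].unique())

    @property
    def roi_versions(self) -> list[str]:
        return sorted(self.frame["roi_version"].unique().tolist())

    @property
    def features(self) -> list[str]:
        return self.frame["feature"].unique().tolist()

    def pivot(self, feature: str, columns: str, roi_version: str | None = None,
              n_bins: int | None = None) -> pd.DataFrame:
        """Subjects x ``columns`` matrix for one feature (NA where flagged)."""
        sub = self.frame[self.frame["feature"] == feature]
        if roi_version is not None:
            sub = sub[sub["roi_version"] == roi_version]
        if n_bins is not None:
            sub = sub[sub["n_bins"] == n_bins]
        return sub.pivot_table(
            index="subject", columns=columns, values="value", dropna=False
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path, keep_default_na=True))

    def __len__(self) -> int:
        return len(self.frame)


def build_table(
    cohort: Sequence[tuple[np.ndarray, np.ndarray]] | Iterable,
    bins: Sequence[int] = DEFAULT_BINS,
    roi_versions: dict[str, Callable[[np.ndarray], np.ndarray]] | None = None,
    subject_ids: Sequence | None = None,
) -> FeatureTable:
    """Extract all 75 features for every subject x bin x ROI-version cell.

    ``cohort`` is a sequence of ``(volume, mask)`` pairs; ``roi_versions``
    maps version label -> mask transform (default only ``original``,
    identity).  Cells whose extraction fails (e.g. a perturbed mask became
    empty) are recorded with a ``na_reason`` instead of being dropped.
    """
    cohort = list(cohort)
    if roi_versions is None:
        roi_versions = {"original": lambda m: m}
    if subject_ids is None:
        subject_ids = list(range(len(cohort)))

    rows = []
    for sid, (vol, mask) in zip(subject_ids, cohort):
        for version, transform in roi_versions.items():
            vmask = transform(mask)
            for nb in bins:
                try:
                    feats = extract_features(vol, vmask, int(nb))
                    for name, value in feats.items():
                        rows.append((sid, version, int(nb), name, value, ""))
                except ValueError as exc:
                    for name in FEATURE_NAMES:
                        rows.append((sid, version, int(nb), name, np.nan, str(exc)))
    return FeatureTable(pd.DataFrame(rows, columns=COLUMNS))
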