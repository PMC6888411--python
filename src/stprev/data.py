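"""Binomial prevalence panels indexed by region x wave (x sex).

The on-disk form is a long CSV with columns ``region, year, sex, cases,
total`` plus optional regional covariate columns (proportions in [0, 1]).
``sex`` is ``m``/``f`` for two-sex panels (joint shared-component modelling)
or ``all`` for single-outcome panels (separate BYM fits).  In memory the
panel is dense arrays aligned with a :class:`~stprev.graph.RegionGraph`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import RegionGraph

__all__ = ["PanelCounts", "COVARIATE_NAMES", "read_panel_csv", "write_panel_csv"]

#: Regional covariates: proportions of the population aged >= 60, overweight
#: (BMI >= 24), ever smokers, and alcohol drinkers.
COVARIATE_NAMES = ("age60plus", "overweight", "ever_smoker", "drinker")

_SEX_LABELS = {1: ("all",), 2: ("m", "f")}


@dataclass(frozen=True)
class PanelCounts:
    """Cases/totals arrays over a region graph and ordered waves.

    ``O`` and ``n`` have shape ``(n_sexes, N, T)`` (``n_sexes`` is 1 for a
    single-outcome panel, 2 for male/female); ``X``, if present, has shape
    ``(N, T, C)`` with covariate proportions shared across sexes.
    """

    graph: RegionGraph
    waves: tuple[int, ...]
    O: np.ndarray = field(repr=False)
    n: np.ndarray = field(repr=False)
    X: np.ndarray | None = field(default=None, repr=False)
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        O = np.asarray(self.O, dtype=np.int64)
        n = np.asarray(self.n, dtype=np.int64)
        object.__setattr__(self, "waves", tuple(int(w) for w in self.waves))
        shape = (O.shape[0], self.graph.n_regions, len(self.waves))
        if O.ndim != 3 or O.shape != shape or n.shape != shape:
            raise ValueError(
                f"O and n must have shape (n_sexes, N, T) = {shape}; "
                f"got {O.shape} and {n.shape}"
            )
        if O.shape[0] not in (1, 2):
            raise ValueError("n_sexes must be 1 or 2")
        if np.any(n <= 0):
            raise ValueError("all totals must be positive")
        if np.any(O < 0) or np.any(O > n):
            raise ValueError("cases must satisfy 0 <= O <= n")
        object.__setattr__(self, "O", O)
        object.__setattr__(self, "n", n)
        if self.X is not None:
            X = np.asarray(self.X, dtype=float)
            exp = (self.graph.n_regions, len(self.waves), len(self.covariate_names))
            if X.shape != exp:
                raise ValueError(f"X must have shape {exp}, got {X.shape}")
            if np.any((X < 0) | (X > 1)):
                raise ValueError("covariates must be proportions in [0, 1]")
            object.__setattr__(self, "X", X)
            object.__setattr__(
                self, "covariate_names", tuple(self.covariate_names)
            )

    @property
    def n_sexes(self) -> int:
        return int(self.O.shape[0])

    @property
    def n_regions(self) -> int:
        return self.graph.n_regions

    @property
    def n_waves(self) -> int:
        return len(self.waves)

    def pooled_prevalence(self, wave: int | None = None) -> float:
        """Cases over totals pooled across regions and sexes."""
        if wave is None:
            return float(self.O.sum() / self.n.sum())
        t = self.waves.index(wave)
        return float(self.O[..., t].sum() / self.n[..., t].sum())

    def sex_prevalence(self, sex_index: int, wave: int) -> float:
        t = self.waves.index(wave)
        return float(self.O[sex_index, :, t].sum() / self.n[sex_index, :, t].sum())

    def fingerprint(self) -> str:
        """Stable content hash used to guard model-comparison tables."""
        import hashlib

        h = hashlib.sha256()
        h.update(",".join(self.graph.region_ids).encode())
        h.update(np.asarray(self.waves).tobytes())
        h.update(self.O.tobytes())
        h.update(self.n.tobytes())
        if self.X is not None:
            h.update(np.round(self.X, 12).tobytes())
        return h.hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        labels = _SEX_LABELS[self.n_sexes]
        rows = []
        for s, lab in enumerate(labels):
            for i, region in enumerate(self.graph.region_ids):
                for t, year in enumerate(self.waves):
                    row = {
                        "region": region,
                        "year": year,
                        "sex": lab,
                        "cases": int(self.O[s, i, t]),
                        "total": int(self.n[s, i, t]),
                    }
                    for c, name in enumerate(self.covariate_names):
                        row[name] = float(self.X[i, t, c])
                    rows.append(row)
        return pd.DataFrame(rows)


def write_panel_csv(panel: PanelCounts, path: str | Path) -> None:
    df = panel.to_frame()
    for name in panel.covariate_names:
        df[name] = df[name].map(lambda v: format(v, ".12g"))
    df.to_csv(path, index=False)


def read_panel_csv(path: str | Path, graph: RegionGraph) -> PanelCounts:
    """Load a long-format panel CSV, validating alignment with ``graph``.

    The header must contain exactly ``region, year, sex, cases, total``
    followed by zero or more known covariate columns; every region x year x
    sex cell must appear exactly once.
    """
    df = pd.read_csv(path)
    required = ["region", "year", "sex", "cases", "total"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"panel CSV missing required columns: {missing}")
    extra = [c for c in df.columns if c not in required]
    unknown = [c for c in extra if c not in COVARIATE_NAMES]
    if unknown:
        raise ValueError(
            f"unknown columns {unknown}; covariates must be among {COVARIATE_NAMES}"
        )
    cov_names = tuple(c for c in COVARIATE_NAMES if c in extra)

    sexes = sorted(set(df["sex"].astype(str)))
    if sexes == ["all"]:
        labels = ("all",)
    elif sexes == ["f", "m"]:
        labels = ("m", "f")
    else:
        raise ValueError(f"sex column must be 'all' or 'm'/'f'; got {sexes}")

    regions_in_file = set(df["region"].astype(str))
    if regions_in_file != set(graph.region_ids):
        raise ValueError(
            "panel regions do not match graph regions: "
            f"panel-only={sorted(regions_in_file - set(graph.region_ids))}, "
            f"graph-only={sorted(set(graph.region_ids) - regions_in_file)}"
        )
    waves = tuple(sorted(set(int(y) for y in df["year"])))

    S, N, T = len(labels), graph.n_regions, len(waves)
    O = np.full((S, N, T), -1, dtype=np.int64)
    n = np.full((S, N, T), -1, dtype=np.int64)
    X = np.full((N, T, len(cov_names)), np.nan) if cov_names else None
    widx = {w: t for t, w in enumerate(waves)}
    sidx = {lab: s for s, lab in enumerate(labels)}
    for _, row in df.iterrows():
        i = graph.index_of(str(row["region"]))
        t = widx[int(row["year"])]
        s = sidx[str(row["sex"])]
        if O[s, i, t] != -1:
            raise ValueError(
                f"duplicate cell region={row['region']} year={row['year']} sex={row['sex']}"
            )
        O[s, i, t] = int(row["cases"])
        n[s, i, t] = int(row["total"])
        for c, name in enumerate(cov_names):
            X[i, t, c] = float(row[name])
    if np.any(O < 0):
        raise ValueError("panel CSV is missing region x year x sex cells")
    return PanelCounts(graph, waves, O, n, X=X, covariate_names=cov_names)
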