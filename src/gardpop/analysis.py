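"""Trajectory statistics: generations, shrinkage, growth correlations,
distributions, environment curves, and PCA embeddings.

All functions consume an in-memory :class:`~gardpop.simulate.Trajectory`
(either fresh from ``run`` or loaded from SQLite) and return tidy pandas
DataFrames ready for CSV export or plotting.

Growth rates are defined between consecutive *stored* snapshots:
``(total_now - total_prev) / (t_now - t_prev)`` in lipids per second, for
vesicles present in both snapshots.  A vesicle that divided within the
interval is retired under its old id and therefore drops out of that
interval automatically — its apparent halving is a division artifact, not
growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .environment import AVOGADRO
from .simulate import Snapshot, Trajectory
from .vesicle import PROPERTY_NAMES

QUANTILES = (0.025, 0.25, 0.50, 0.75, 0.975)
_QCOLS = ["q025", "q25", "q50", "q75", "q975"]


def mean_generation_series(traj: Trajectory) -> pd.DataFrame:
    """Per snapshot: mean generation over living vesicles (population age)."""
    if not traj.snapshots:
        raise ValueError("empty trajectory")
    rows = [
        (s.time, float(s.generation.mean()) if s.n_vesicles else np.nan, s.n_vesicles)
        for s in traj.snapshots
    ]
    return pd.DataFrame(rows, columns=["time", "mean_generation", "n_vesicles"])


def time_to_mean_generation(traj: Trajectory, g: float) -> float | None:
    """First time the mean generation reaches ``g``, linearly interpolated
    between the bracketing snapshots.  ``None`` if the run never got there."""
    series = mean_generation_series(traj)
    t = series["time"].to_numpy()
    y = series["mean_generation"].to_numpy()
    if g <= y[0]:
        return float(t[0])
    above = np.nonzero(y >= g)[0]
    if above.size == 0:
        return None
    k = int(above[0])
    t0, t1, y0, y1 = t[k - 1], t[k], y[k - 1], y[k]
    if y1 == y0:
        return float(t1)
    return float(t0 + (g - y0) * (t1 - t0) / (y1 - y0))


def _match_ids(prev: Snapshot, now: Snapshot) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays into (prev, now) for vesicle ids present in both."""
    _, i_prev, i_now = np.intersect1d(
        prev.vesicle_id, now.vesicle_id, return_indices=True
    )
    return i_prev, i_now


def shrinking_fraction_series(traj: Trajectory) -> pd.DataFrame:
    """Fraction of tracked vesicles whose total strictly decreased over each
    snapshot interval.  Vesicles born or retired within the interval are not
    tracked for it."""
    if len(traj.snapshots) < 2:
        raise ValueError("need at least two snapshots")
    rows = []
    for prev, now in zip(traj.snapshots, traj.snapshots[1:]):
        i_prev, i_now = _match_ids(prev, now)
        n = i_prev.size
        frac = (
            float((now.total[i_now] < prev.total[i_prev]).sum() / n) if n else np.nan
        )
        rows.append((now.time, frac, n))
    return pd.DataFrame(rows, columns=["time", "shrinking_fraction", "n_tracked"])


def nearest_snapshot_index(traj: Trajectory, t: float) -> int:
    """Index of the snapshot closest to ``t`` (ties go to the earlier one)."""
    times = traj.times
    return int(np.argmin(np.abs(times - t)))


def growth_records(traj: Trajectory, t: float) -> pd.DataFrame:
    """Per-vesicle growth rates and predictors at the snapshot nearest ``t``.

    Columns: vesicle_id, generation, growth_rate (lipids/s), the six vesicle
    properties, and the per-class mole fractions.
    """
    k = nearest_snapshot_index(traj, t)
    if k == 0:
        k = 1
    if k >= len(traj.snapshots):
        raise ValueError("trajectory too short for growth records")
    prev, now = traj.snapshots[k - 1], traj.snapshots[k]
    i_prev, i_now = _match_ids(prev, now)
    dt = now.time - prev.time
    growth = (now.total[i_now] - prev.total[i_prev]) / dt
    data = {
        "vesicle_id": now.vesicle_id[i_now],
        "generation": now.generation[i_now],
        "growth_rate": growth,
    }
    for j, name in enumerate(PROPERTY_NAMES):
        data[name] = now.properties[i_now, j]
    totals = now.total[i_now].astype(float)
    for c, cls in enumerate(traj.catalog.classes):
        data[cls] = now.class_counts[i_now, c] / totals
    df = pd.DataFrame(data)
    df.attrs["time"] = now.time
    return df


def growth_correlations(
    traj: Trajectory, t: float, variables: list[str] | None = None
) -> pd.DataFrame:
    """Univariate Pearson correlations of growth rate against each predictor
    across vesicles at the snapshot nearest ``t``.

    Returns one row per variable with Pearson ``r``, two-sided ``p``, the
    adjusted R^2 of the univariate linear fit, and a significance flag at
    p <= 0.05.  Zero-variance predictors yield ``r = NaN`` with a diagnostic
    note instead of a spurious value.
    """
    rec = growth_records(traj, t)
    if len(rec) < 3:
        raise ValueError(f"need >= 3 vesicles near t={t}, got {len(rec)}")
    if variables is None:
        variables = list(PROPERTY_NAMES) + list(traj.catalog.classes)
    y = rec["growth_rate"].to_numpy(dtype=float)
    n = len(y)
    rows = []
    for var in variables:
        x = rec[var].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((var, np.nan, np.nan, np.nan, False, "zero variance"))
            continue
        r, p = stats.pearsonr(x, y)
        adj = 1.0 - (1.0 - r * r) * (n - 1) / (n - 2)
        rows.append((var, r, p, adj, bool(p <= 0.05), ""))
    out = pd.DataFrame(
        rows, columns=["variable", "r", "p", "adjusted_r2", "significant", "note"]
    )
    out.attrs["time"] = rec.attrs["time"]
    out.attrs["n_vesicles"] = n
    return out


def _summaries(values: np.ndarray) -> list[float]:
    qs = np.quantile(values, QUANTILES)
    sd = float(values.std(ddof=0)) if values.size else np.nan
    return [float(values.mean()), sd, *qs.tolist()]


def composition_distribution(traj: Trajectory) -> pd.DataFrame:
    """Across-vesicle distribution of per-class mole fractions at each
    snapshot: mean, SD, and 2.5/25/50/75/97.5% quantiles."""
    rows = []
    for s in traj.snapshots:
        if s.n_vesicles == 0:
            continue
        frac = s.class_counts / s.total[:, None].astype(float)
        for c, cls in enumerate(traj.catalog.classes):
            rows.append([s.time, cls, s.n_vesicles, *_summaries(frac[:, c])])
    return pd.DataFrame(
        rows, columns=["time", "variable", "n_vesicles", "mean", "sd", *_QCOLS]
    )


def property_distribution(traj: Trajectory) -> pd.DataFrame:
    """Same summaries as :func:`composition_distribution`, for the six
    vesicle properties."""
    rows = []
    for s in traj.snapshots:
        if s.n_vesicles == 0:
            continue
        for j, name in enumerate(PROPERTY_NAMES):
            rows.append([s.time, name, s.n_vesicles, *_summaries(s.properties[:, j])])
    return pd.DataFrame(
        rows, columns=["time", "variable", "n_vesicles", "mean", "sd", *_QCOLS]
    )


def environment_series(
    traj: Trajectory, species_ids: list[str] | None = None
) -> pd.DataFrame:
    """Molar concentration of the requested species at every snapshot."""
    if species_ids is None:
        species_ids = [s.species_id for s in traj.catalog]
    idx = [traj.catalog.index[sid] for sid in species_ids]
    rows = []
    for s in traj.snapshots:
        conc = s.env_free / (AVOGADRO * traj.volume)
        for sid, j in zip(species_ids, idx):
            rows.append((s.time, sid, int(s.env_free[j]), float(conc[j])))
    return pd.DataFrame(
        rows, columns=["time", "species_id", "free_count", "concentration_M"]
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame            # pc1, pc2, generation, time, vesicle_id
    explained_variance: np.ndarray  # all components
    total_variance: float

    @property
    def retained_variance(self) -> float:
        return float(self.explained_variance[:2].sum())


def pca_embedding(traj: Trajectory, basis: str = "compositions") -> PCAResult:
    """Project pooled per-vesicle rows onto the first two principal components.

    ``basis="compositions"`` uses per-class mole fractions;
    ``basis="properties"`` uses the six properties, standardized column-wise
    (they have wildly different scales).  Scores carry generation labels so
    the spread of late generations can be compared between modes.
    """
    from sklearn.decomposition import PCA

    if basis not in ("compositions", "properties"):
        raise ValueError("basis must be 'compositions' or 'properties'")
    blocks, gens, times, vids = [], [], [], []
    for s in traj.snapshots:
        if s.n_vesicles == 0:
            continue
        if basis == "compositions":
            blocks.append(s.class_counts / s.total[:, None].astype(float))
        else:
            blocks.append(s.properties)
        gens.append(s.generation)
        times.append(np.full(s.n_vesicles, s.time))
        vids.append(s.vesicle_id)
    x = np.concatenate(blocks, axis=0)
    if x.shape[0] < 2:
        raise ValueError("need at least two vesicle records for a PCA")
    if basis == "properties":
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=min(x.shape))
    scores_full = pca.fit_transform(x)
    scores = pd.DataFrame(
        {
            "pc1": scores_full[:, 0],
            "pc2": scores_full[:, 1] if scores_full.shape[1] > 1 else 0.0,
            "generation": np.concatenate(gens),
            "time": np.concatenate(times),
            "vesicle_id": np.concatenate(vids),
        }
    )
    total_var = float(x.var(axis=0, ddof=1).sum())
    return PCAResult(
        scores=scores,
        explained_variance=pca.explained_variance_.copy(),
        total_variance=total_var,
    )


def steady_state_time(
    series: pd.Series, window: float, tol: float
) -> float | None:
    """Earliest time after which the series' windowed means stop moving.

    ``series`` is indexed by time.  For each sample time ``t_k`` the windowed
    mean over ``[t_k, t_k + window]`` is computed; the function returns the
    earliest ``t_k`` such that all subsequent windowed means stay within
    ``tol * (series range)`` of each other.  The qualifying tail must span at
    least one window, so a series still drifting at the end (e.g. a pure
    ramp as tol -> 0) yields ``None``.
    """
    t = np.asarray(series.index, dtype=float)
    y = np.asarray(series.to_numpy(), dtype=float)
    if t.size == 0:
        raise ValueError("empty series")
    rng_y = float(np.ptp(y))
    if rng_y == 0:
        return float(t[0])
    means = np.array(
        [y[(t >= tk) & (t <= tk + window)].mean() for tk in t]
    )
    for k in range(t.size):
        if t[-1] - t[k] < window:
            break
        tail = means[k:]
        if np.ptp(tail) < tol * rng_y:
            return float(t[k])
    return None
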