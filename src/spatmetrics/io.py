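"""File formats, manifests and bundled test fixtures.

Everything is plain text: stem maps are CSV with an ``x,y`` header and an
optional ``species`` column; metric curves are TSV with ``#``-prefixed
metadata lines; every CLI command writes a JSON manifest recording the
command, parameters, master seed and scale factors needed to re-run it.
"""

from __future__ import annotations

import json
import datetime
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import Landscape, PointPattern
from .metrics import MetricCurve
from .simulate import ThomasParams, simulate_csr, simulate_thomas

__all__ = [
    "read_stem_map",
    "write_pattern",
    "write_curve",
    "read_curve",
    "Manifest",
    "make_fixtures",
]


def read_stem_map(
    path, width: float, height: float, jitter: float | None = None
) -> dict[str, PointPattern]:
    """Read a stem-map CSV into one point pattern per species.

    The file must have ``x`` and ``y`` columns; a ``species`` column is
    optional (without it every stem belongs to a single unnamed species).
    Out-of-window coordinates and duplicate coordinates within a species are
    reported with their row numbers; duplicates can instead be jittered by
    passing a small ``jitter`` magnitude.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: stem map is empty")
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    land = Landscape(width, height)
    out_of_bounds = ~(
        (df["x"] >= 0) & (df["x"] <= width) & (df["y"] >= 0) & (df["y"] <= height)
    )
    if out_of_bounds.any():
        rows = (df.index[out_of_bounds] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: coordinates outside window at file rows {rows[:10]}")
    if "species" in df.columns:
        groups = dict(tuple(df.groupby("species", sort=True)))
    else:
        groups = {"species_1": df}
    patterns = {}
    for name, sub in groups.items():
        coords = sub[["x", "y"]].to_numpy(dtype=float)
        try:
            patterns[str(name)] = PointPattern(coords, land, jitter=jitter)
        except ValueError as err:
            # map duplicate indices back to file rows
            dup_rows = (sub.index[_dup_mask(coords)] + 2).tolist()
            raise ValueError(
                f"{path}: species {name!r}: duplicate coordinates at file rows "
                f"{dup_rows[:10]}"
            ) from err
    return patterns


def _dup_mask(coords: np.ndarray) -> np.ndarray:
    _, first = np.unique(coords, axis=0, return_index=True)
    mask = np.ones(coords.shape[0], dtype=bool)
    mask[first] = False
    return mask


def write_pattern(pattern: PointPattern, path, species: str | None = None) -> None:
    """Write a pattern as an x,y[,species] CSV."""
    df = pd.DataFrame(pattern.coords, columns=["x", "y"])
    if species is not None:
        df["species"] = species
    df.to_csv(path, index=False)


_CURVE_COLS = ("abscissa", "ordinate", "support", "mean")


def write_curve(curve: MetricCurve, path) -> None:
    """Serialize a MetricCurve as TSV with # metadata header lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kind\t{curve.kind}\n")
        if curve.plot_side is not None:
            fh.write(f"# plot_side\t{curve.plot_side!r}\n")
        if curve.scale_factor is not None:
            fh.write(f"# scale_factor\t{curve.scale_factor!r}\n")
        for key, val in sorted(curve.meta.items()):
            fh.write(f"# {key}\t{json.dumps(val)}\n")
        fh.write("\t".join(_CURVE_COLS) + "\n")
        means = curve.mean if curve.mean is not None else [""] * curve.abscissa.size
        for a, o, s, m in zip(curve.abscissa, curve.ordinate, curve.support, means):
            mtxt = repr(float(m)) if m != "" else ""
            fh.write(f"{float(a)!r}\t{float(o)!r}\t{int(s)}\t{mtxt}\n")


def read_curve(path, expect_kind: str | None = None) -> MetricCurve:
    """Read a MetricCurve TSV written by :func:`write_curve` (exact round trip)."""
    path = Path(path)
    meta: dict = {}
    kind = plot_side = scale_factor = None
    rows = []
    with path.open() as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, val = line[2:].partition("\t")
                if key == "kind":
                    kind = val
                elif key == "plot_side":
                    plot_side = float(val)
                elif key == "scale_factor":
                    scale_factor = float(val)
                else:
                    meta[key] = json.loads(val)
            elif not header_seen:
                if line.split("\t") != list(_CURVE_COLS):
                    raise ValueError(f"{path}: unexpected column header {line!r}")
                header_seen = True
            elif line:
                rows.append(line.split("\t"))
    if kind is None:
        raise ValueError(f"{path}: missing '# kind' metadata line")
    if expect_kind is not None and kind != expect_kind:
        raise ValueError(f"{path}: expected kind {expect_kind!r}, found {kind!r}")
    absc = np.array([float(r[0]) for r in rows])
    ordi = np.array([float(r[1]) for r in rows])
    supp = np.array([int(r[2]) for r in rows])
    has_mean = any(len(r) > 3 and r[3] != "" for r in rows)
    mean = np.array([float(r[3]) for r in rows]) if has_mean else None
    return MetricCurve(
        kind=kind, abscissa=absc, ordinate=ordi, support=supp,
        plot_side=plot_side, mean=mean, scale_factor=scale_factor, meta=meta,
    )


@dataclass
class Manifest:
    """Record of one CLI invocation, sufficient to re-run it exactly."""

    command: str
    parameters: dict
    seed: int | None = None
    scale_factors: dict = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def write(self, path) -> None:
        d = asdict(self)
        if not d["timestamp"]:
            d["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
        Path(path).write_text(json.dumps(d, indent=2, default=str) + "\n")

    @classmethod
    def read(cls, path) -> "Manifest":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

#: three points in a 2 x 2 window whose quadrat counts at side 1 are
#: {1, 1, 1, 0}: the hand-countable toy pattern used throughout the tests
TOY_THREE_POINTS = ((0.5, 0.5), (1.5, 0.5), (1.5, 1.5))


def make_fixtures(seed: int, outdir) -> dict[str, Path]:
    """Deterministically generate the tiny datasets used by the unit tests.

    Writes a 3-point toy pattern, a small CSR pattern, a small Thomas
    pattern and a 2-species stem map, all loadable through
    :func:`read_stem_map`.  Returns name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    toy = PointPattern(np.array(TOY_THREE_POINTS), Landscape(2.0, 2.0))
    paths["toy_three_points"] = outdir / "toy_three_points.csv"
    write_pattern(toy, paths["toy_three_points"])

    csr = simulate_csr(200, Landscape(50.0, 50.0), seed)
    paths["small_csr"] = outdir / "small_csr.csv"
    write_pattern(csr, paths["small_csr"])

    thomas = simulate_thomas(
        ThomasParams(rho=0.02, mu_cluster=4.0, sigma_cluster=1.5),
        Landscape(50.0, 50.0),
        seed + 1,
    )
    paths["small_thomas"] = outdir / "small_thomas.csv"
    write_pattern(thomas, paths["small_thomas"])

    a = simulate_csr(80, Landscape(100.0, 100.0), seed + 2)
    b = simulate_thomas(
        ThomasParams(rho=0.005, mu_cluster=5.0, sigma_cluster=3.0),
        Landscape(100.0, 100.0),
        seed + 3,
    )
    df = pd.concat(
        [
            pd.DataFrame(a.coords, columns=["x", "y"]).assign(species="uniformis"),
            pd.DataFrame(b.coords, columns=["x", "y"]).assign(species="aggregata"),
        ]
    )
    paths["two_species"] = outdir / "two_species.csv"
    df.to_csv(paths["two_species"], index=False)
    return paths
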