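"""Reading oxDNA trajectories and spectrum/fit-report serialisation.

The oxDNA dialect understood here: a topology file whose first line is
``N_nucleotides N_strands`` followed by one row per nucleotide
(``strand base neighbour_3' neighbour_5'``), and a configuration file of one
or more snapshots, each a three-line header (``t = …``, ``b = Lx Ly Lz``,
``E = …``) followed by one row per nucleotide: position (3), backbone-base
versor a1 (3), base-normal versor a3 (3), then velocities (ignored).

Complementary-duplex pairing: equal-length strand pairs (1,2), (3,4), …;
nucleotide i of the first strand pairs with the reverse-ordered nucleotide of
the second.  The dsDNA segment is the base pair: its position is the pair
midpoint, its direction the normalised difference of the two base normals
(near-antiparallel on the two strands, so the difference is a stable duplex
axis proxy).  The sign of the direction is irrelevant downstream (all
estimator weights are even in t).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult
from .spectrum import OBSERVABLES, ChainConfiguration, FluctuationSpectrum

__all__ = [
    "TrajectorySource",
    "read_oxdna",
    "write_spectrum",
    "read_spectrum",
    "write_fit_result",
]

_SPECTRUM_COLUMNS = ["q", "n_qvec"] + [
    c for name in OBSERVABLES for c in (name, f"{name}_err")
]
_META_KEYS = ("N0", "rho0", "L0", "n_configs", "block_size")


@dataclasses.dataclass(frozen=True)
class TrajectorySource:
    """Paths of one oxDNA topology and its configuration snapshots."""

    topology: Path
    configurations: tuple[Path, ...]
    stride: int = 1

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


class OxdnaParseError(ValueError):
    """Malformed oxDNA topology/configuration content (carries a line number)."""


def _read_topology(path: Path) -> list[np.ndarray]:
    """Return per-strand nucleotide index lists, in file order."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise OxdnaParseError(f"{path}: empty topology")
    try:
        n_nuc, n_strands = map(int, lines[0].split()[:2])
    except Exception as exc:
        raise OxdnaParseError(f"{path}:1: bad header {lines[0]!r}") from exc
    strands: dict[int, list[int]] = {}
    body = [ln for ln in lines[1:] if ln.strip()]
    if len(body) != n_nuc:
        raise OxdnaParseError(
            f"{path}: header declares {n_nuc} nucleotides, found {len(body)} rows"
        )
    for i, ln in enumerate(body):
        parts = ln.split()
        try:
            sid = int(parts[0])
        except Exception as exc:
            raise OxdnaParseError(f"{path}:{i + 2}: bad topology row {ln!r}") from exc
        strands.setdefault(sid, []).append(i)
    if len(strands) != n_strands:
        raise OxdnaParseError(
            f"{path}: header declares {n_strands} strands, found {len(strands)}"
        )
    return [np.array(strands[sid]) for sid in sorted(strands)]


def _iter_conf_snapshots(path: Path, n_nuc: int):
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].lstrip().startswith("t"):
            raise OxdnaParseError(f"{path}:{i + 1}: expected 't = ...' header, got {lines[i]!r}")
        try:
            box_vals = np.array(lines[i + 1].split("=")[1].split(), dtype=float)
        except Exception as exc:
            raise OxdnaParseError(f"{path}:{i + 2}: bad box line") from exc
        if not np.allclose(box_vals, box_vals[0]):
            raise OxdnaParseError(f"{path}:{i + 2}: only cubic boxes are supported")
        rows = lines[i + 3 : i + 3 + n_nuc]
        if len(rows) < n_nuc:
            raise OxdnaParseError(f"{path}:{i + 3}: truncated snapshot ({len(rows)}/{n_nuc} rows)")
        try:
            data = np.array([r.split()[:9] for r in rows], dtype=float)
        except Exception as exc:
            raise OxdnaParseError(f"{path}:{i + 4}: bad configuration row") from exc
        yield float(box_vals[0]), data[:, 0:3], data[:, 6:9]
        i += 3 + n_nuc


def read_oxdna(src: TrajectorySource | Path | str, conf: Path | str | None = None) -> list[ChainConfiguration]:
    """Read an oxDNA duplex trajectory into chain configurations.

    Accepts either a :class:`TrajectorySource` or ``(topology, configuration)``
    paths.  Each pair of equal-length strands becomes one chain of base-pair
    segments.
    """
    if not isinstance(src, TrajectorySource):
        if conf is None:
            raise ValueError("read_oxdna needs a TrajectorySource or (topology, conf) paths")
        src = TrajectorySource(topology=Path(src), configurations=(Path(conf),))

    strands = _read_topology(src.topology)
    if len(strands) % 2 != 0:
        raise OxdnaParseError(f"{src.topology}: odd number of strands; cannot pair duplexes")
    duplexes = []
    for d in range(len(strands) // 2):
        s1, s2 = strands[2 * d], strands[2 * d + 1]
        if len(s1) != len(s2):
            raise OxdnaParseError(
                f"{src.topology}: strands {2 * d + 1} and {2 * d + 2} have unequal lengths"
            )
        duplexes.append((s1, s2[::-1]))  # antiparallel: reverse index order
    n_nuc = sum(len(s) for s in strands)

    configs: list[ChainConfiguration] = []
    for conf_path in src.configurations:
        for k, (box, pos, a3) in enumerate(_iter_conf_snapshots(conf_path, n_nuc)):
            if k % src.stride:
                continue
            positions, directions, chain_id = [], [], []
            for cid, (s1, s2) in enumerate(duplexes):
                mid = 0.5 * (pos[s1] + pos[s2])
                d = a3[s1] - a3[s2]
                norm = np.linalg.norm(d, axis=1, keepdims=True)
                if np.any(norm < 1e-12):
                    raise OxdnaParseError(
                        f"{conf_path}: parallel base normals in duplex {cid}; cannot orient segment"
                    )
                positions.append(mid % box)
                directions.append(d / norm)
                chain_id.append(np.full(len(s1), cid))
            configs.append(
                ChainConfiguration(
                    box=box,
                    positions=np.concatenate(positions),
                    directions=np.concatenate(directions),
                    chain_id=np.concatenate(chain_id),
                )
            )
    return configs


def write_spectrum(spectrum: FluctuationSpectrum, path: Path | str) -> None:
    """Write a spectrum as a delimited text table with a metadata header."""
    path = Path(path)
    df = spectrum.to_frame()
    header = "# " + " ".join(f"{k}={spectrum.meta[k]:.17g}" for k in _META_KEYS)
    with path.open("w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_spectrum(path: Path | str) -> FluctuationSpectrum:
    """Read a spectrum table written by :func:`write_spectrum` (lossless)."""
    path = Path(path)
    meta: dict[str, float] = {}
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                meta[k] = float(v)
            df = pd.read_csv(fh, sep="\t")
        else:
            df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: unsupported spectrum schema, missing column(s) {missing}")
    q = df["q"].to_numpy(float)
    if np.any(np.diff(q) <= 0):
        raise ValueError(f"{path}: q column must be strictly increasing")
    for k in _META_KEYS:
        meta.setdefault(k, np.nan)
    return FluctuationSpectrum(
        q=q,
        n_qvec=df["n_qvec"].to_numpy(),
        est={name: df[name].to_numpy(float) for name in OBSERVABLES},
        err={name: df[f"{name}_err"].to_numpy(float) for name in OBSERVABLES},
        meta=meta,
    )


def write_fit_result(fit: FitResult, path: Path | str, **provenance) -> None:
    """Serialise a fit result (params, errors, settings, provenance) as JSON."""
    Path(path).write_text(json.dumps(fit.to_json_dict(**provenance), indent=2) + "\n")
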