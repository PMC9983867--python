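"""Readers/writers: expression matrices (TSV/CSV/MTX), HDF5 population
archives, JSON/YAML configs and run manifests."""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dynamics import DevelopmentParams
from .empirical import LabeledExpressionMatrix
from .evolution import (
    EvolutionConfig,
    EvolutionResult,
    EvolutionWorld,
    GenerationStats,
    Population,
)

__all__ = [
    "read_expression",
    "write_expression",
    "write_genotype_tsv",
    "save_population",
    "load_population",
    "save_evolution",
    "load_evolution",
    "load_config",
    "RunManifest",
]

ARCHIVE_VERSION = 1


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _read_two_column(path, name: str, value_col: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 1:
        # bare list of ids -> flags
        return pd.Series(True, index=pd.Index(df.iloc[:, 0].astype(str)))
    if df.shape[1] != 2:
        raise ValueError(f"{name} file must have 1 or 2 columns, got {df.shape[1]}")
    idx = pd.Index(df.iloc[:, 0].astype(str))
    return pd.Series(df.iloc[:, 1].values, index=idx, name=value_col)


def read_expression(path, labels_path, polycomb_path=None) -> LabeledExpressionMatrix:
    """Read a labeled expression matrix.

    ``path`` is either a TSV/CSV of genes x cells (first column = gene ids,
    header = cell ids) or a MatrixMarket ``.mtx`` file, in which case
    sibling files ``<stem>_genes.tsv`` and ``<stem>_cells.tsv`` supply the
    row and column ids. ``labels_path`` is a two-column TSV (cell id,
    category); every cell in the matrix must be labeled. ``polycomb_path``
    is a gene list or two-column (gene id, 0/1) TSV.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        raw = mmread(path)
        mat = raw.toarray() if hasattr(raw, "toarray") else np.asarray(raw)
        genes = pd.read_csv(path.with_name(path.stem + "_genes.tsv"),
                            sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(path.with_name(path.stem + "_cells.tsv"),
                            sep="\t", header=None)[0].astype(str)
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(genes)} genes x {len(cells)} cells")
        values = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                              columns=pd.Index(cells, name="cell"))
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        values = pd.read_csv(path, sep=sep, index_col=0)
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)

    labels = _read_two_column(labels_path, "labels", "category").astype(str)
    missing = values.columns.difference(labels.index)
    if len(missing):
        raise ValueError(f"label file is missing cells: {list(missing[:5])}")
    if polycomb_path is not None:
        pc = _read_two_column(polycomb_path, "polycomb", "flag")
        pc = pc.astype(bool) if pc.dtype != object else pc.astype(int).astype(bool)
        polycomb = pc.reindex(values.index, fill_value=False)
    else:
        polycomb = pd.Series(False, index=values.index)
    return LabeledExpressionMatrix(values=values,
                                   cell_category=labels.reindex(values.columns),
                                   polycomb=polycomb)


def write_expression(matrix: LabeledExpressionMatrix, out_dir,
                     stem: str = "expression", fmt: str = "tsv") -> dict[str, Path]:
    """Write a matrix plus its label and polycomb files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if fmt == "mtx":
        from scipy.io import mmwrite

        mpath = out / f"{stem}.mtx"
        mmwrite(mpath, np.asarray(matrix.values.values))
        matrix.gene_ids.to_series().to_csv(out / f"{stem}_genes.tsv",
                                           sep="\t", header=False, index=False)
        matrix.cell_ids.to_series().to_csv(out / f"{stem}_cells.tsv",
                                           sep="\t", header=False, index=False)
        paths["genes"] = out / f"{stem}_genes.tsv"
        paths["cells"] = out / f"{stem}_cells.tsv"
    elif fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        mpath = out / f"{stem}.{fmt}"
        matrix.values.to_csv(mpath, sep=sep)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    paths["matrix"] = mpath
    lpath = out / f"{stem}_labels.tsv"
    matrix.cell_category.to_csv(lpath, sep="\t", header=False)
    paths["labels"] = lpath
    ppath = out / f"{stem}_polycomb.tsv"
    matrix.polycomb.astype(int).to_csv(ppath, sep="\t", header=False)
    paths["polycomb"] = ppath
    return paths


def write_genotype_tsv(genotype, out_dir, stem: str = "genotype") -> dict[str, Path]:
    """Dump a genotype's matrices as plain TSV files for inspection."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (("w_gg", genotype.w_gg), ("w_ge", genotype.w_ge),
                      ("theta", genotype.theta.astype(int))):
        path = out / f"{stem}_{name}.tsv"
        np.savetxt(path, arr, fmt="%.17g" if name != "theta" else "%d",
                   delimiter="\t")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# population archives (HDF5)
# ---------------------------------------------------------------------------

def _write_world(grp: h5py.Group, world: EvolutionWorld) -> None:
    for f in ("env1", "env2", "s_opt1", "s_opt2", "init1", "init2"):
        grp.create_dataset(f, data=getattr(world, f))
    grp.attrs["delta_e"] = world.delta_e
    grp.attrs["delta_s"] = world.delta_s


def _read_world(grp: h5py.Group) -> EvolutionWorld:
    return EvolutionWorld(
        **{f: grp[f][...] for f in ("env1", "env2", "s_opt1", "s_opt2",
                                    "init1", "init2")},
        delta_e=float(grp.attrs["delta_e"]),
        delta_s=float(grp.attrs["delta_s"]),
    )


_POP_FIELDS = ("w_gg", "w_ge", "theta", "s1", "s2",
               "silenced_by1", "silenced_by2", "fitness")


def _write_pop(grp: h5py.Group, pop: Population) -> None:
    for f in _POP_FIELDS:
        grp.create_dataset(f, data=getattr(pop, f))


def _read_pop(grp: h5py.Group) -> Population:
    arrs = {f: grp[f][...] for f in _POP_FIELDS}
    for f in ("theta", "silenced_by1", "silenced_by2"):
        arrs[f] = arrs[f].astype(bool)
    return Population(**arrs)


def save_population(path, population: Population, world: EvolutionWorld,
                    config: EvolutionConfig | None = None,
                    rng: np.random.Generator | None = None,
                    stats: list[GenerationStats] | None = None,
                    checkpoints: dict[int, Population] | None = None,
                    generation: int | None = None) -> None:
    """Losslessly archive a population (and optionally its whole run state)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = ARCHIVE_VERSION
        f.attrs["package"] = "pliancy"
        _write_pop(f.create_group("population"), population)
        _write_world(f.create_group("world"), world)
        if config is not None:
            cfg = dataclasses.asdict(config)
            cfg["dev"] = dataclasses.asdict(config.dev)
            f.attrs["config_json"] = json.dumps(cfg)
        if rng is not None:
            f.attrs["rng_state_json"] = json.dumps(rng.bit_generator.state)
        if generation is not None:
            f.attrs["generation"] = generation
        if stats:
            rows = [dataclasses.astuple(s) for s in stats]
            names = [fld.name for fld in dataclasses.fields(GenerationStats)]
            rec = np.rec.fromrecords(rows, names=names)
            f.create_dataset("stats", data=rec)
        if checkpoints:
            g = f.create_group("checkpoints")
            for gen, pop in checkpoints.items():
                _write_pop(g.create_group(str(gen)), pop)


def load_population(path):
    """Load an archive written by :func:`save_population`.

    Returns a dict with keys ``population``, ``world`` and, when present,
    ``config``, ``rng``, ``stats``, ``checkpoints``, ``generation``.
    """
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise OSError(f"cannot read population archive {path}: {e}") from e
    with f:
        version = f.attrs.get("format_version")
        if version != ARCHIVE_VERSION:
            raise ValueError(
                f"archive format version {version!r} not supported "
                f"(expected {ARCHIVE_VERSION})")
        out = {
            "population": _read_pop(f["population"]),
            "world": _read_world(f["world"]),
        }
        if "config_json" in f.attrs:
            cfg = json.loads(f.attrs["config_json"])
            cfg["dev"] = DevelopmentParams(**cfg["dev"])
            cfg["checkpoints"] = tuple(cfg["checkpoints"])
            out["config"] = EvolutionConfig(**cfg)
        if "rng_state_json" in f.attrs:
            state = json.loads(f.attrs["rng_state_json"])
            rng = np.random.default_rng()
            rng.bit_generator.state = state
            out["rng"] = rng
        if "generation" in f.attrs:
            out["generation"] = int(f.attrs["generation"])
        if "stats" in f:
            rec = f["stats"][...]
            out["stats"] = [GenerationStats(*[r[n] for n in rec.dtype.names])
                            for r in rec]
        if "checkpoints" in f:
            out["checkpoints"] = {int(k): _read_pop(f["checkpoints"][k])
                                  for k in f["checkpoints"]}
    return out


def save_evolution(path, result: EvolutionResult,
                   rng: np.random.Generator | None = None) -> None:
    save_population(path, result.population, result.world,
                    config=result.config, rng=rng, stats=result.stats,
                    checkpoints=result.checkpoints,
                    generation=result.config.generations)


def load_evolution(path) -> EvolutionResult:
    d = load_population(path)
    return EvolutionResult(world=d["world"], population=d["population"],
                           stats=d.get("stats", []),
                           checkpoints=d.get("checkpoints", {}),
                           config=d["config"])


# ---------------------------------------------------------------------------
# configs and manifests
# ---------------------------------------------------------------------------

def load_config(path) -> EvolutionConfig:
    """Build an :class:`EvolutionConfig` from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    dev = raw.pop("dev", None)
    if "checkpoints" in raw:
        raw["checkpoints"] = tuple(raw["checkpoints"])
    known = {f.name for f in dataclasses.fields(EvolutionConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if dev is not None:
        raw["dev"] = DevelopmentParams(**dev)
    return EvolutionConfig(**raw)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted once per CLI run."""

    command: str
    config: dict
    seed: int | None
    package_version: str
    started: str
    finished: str
    inputs: dict[str, str]
    outputs: dict[str, str]

    @classmethod
    def start(cls, command: str, config: dict, seed: int | None) -> "RunManifest":
        from . import __version__

        now = datetime.datetime.now(datetime.timezone.utc).isoformat()
        return cls(command=command, config=config, seed=seed,
                   package_version=__version__, started=now, finished="",
                   inputs={}, outputs={})

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _digest(Path(path))

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _digest(Path(path))

    def write(self, path) -> None:
        self.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
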