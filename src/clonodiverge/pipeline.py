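"""End-to-end orchestration: tests → heritability → coding → parsimony + UPGMA/AU.

``run_pipeline`` is a pure function of (observations, character specs,
config, seed): it writes the per-stage result files plus a reproducibility
manifest with a digest of every output, and reruns with the same inputs
produce identical digests for the deterministic stages (the bootstrap is
seeded, so in practice for all stages).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from .charstats import divergence_test, strain_profile, summarize_tests, tests_to_frame
from .clustering import DEFAULT_SCALES, euclidean_distances, multiscale_bootstrap, scaled_mean_matrix, upgma
from .coding import build_matrix
from .data_io import (
    CharacterSpec,
    ObservationTable,
    ValidationError,
    read_observations,
    read_specs,
    write_matrix_csv,
    write_nexus_matrix,
    write_tree,
)
from .heritability import heritability_table
from .parsimony import branch_and_bound, mp_consensus, root_between, strict_consensus

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("clonodiverge")

DEFAULT_CONFIG = {
    "alpha": 0.05,
    "clade_a": [],
    "clade_b": [],
    "n_boot": 1000,
    "scales": list(DEFAULT_SCALES),
    "seed": 1,
    "restandardize": True,
}


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    clade_a: tuple[str, ...] = ()
    clade_b: tuple[str, ...] = ()
    n_boot: int = 1000
    scales: tuple[float, ...] = DEFAULT_SCALES
    seed: int = 1
    restandardize: bool = True

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "PipelineConfig":
        merged = {**DEFAULT_CONFIG, **dict(cfg)}
        return cls(
            alpha=float(merged["alpha"]),
            clade_a=tuple(merged["clade_a"]),
            clade_b=tuple(merged["clade_b"]),
            n_boot=int(merged["n_boot"]),
            scales=tuple(merged["scales"]),
            seed=int(merged["seed"]),
            restandardize=bool(merged["restandardize"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    tests: pd.DataFrame
    heritability: pd.DataFrame
    matrix: object
    tree_set: object
    consensus: object
    dendrogram: object
    support: pd.DataFrame
    manifest: dict
    outdir: Path


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(obs: str | Path | ObservationTable,
                 specs: str | Path | Mapping[str, CharacterSpec],
                 config: Mapping | PipelineConfig | str | Path | None = None,
                 outdir: str | Path = "results") -> PipelineResult:
    """Run the full analysis and write the result bundle to ``outdir``.

    Stages: per-character divergence tests, heritability of the
    significant characters, binary matrix coding, exact parsimony with
    strict consensus (rooted between the configured clades when given),
    and the UPGMA dendrogram with multiscale-bootstrap AU support.
    """
    if isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_yaml(config)
    elif isinstance(config, PipelineConfig):
        cfg = config
    else:
        cfg = PipelineConfig.from_mapping(config or {})

    if not isinstance(specs, Mapping):
        specs = read_specs(specs)
    if not isinstance(obs, ObservationTable):
        obs = read_observations(obs, specs)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                log.info("stage %s ...", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None:
                    log.error("stage %s failed: %s", name, exc)
                return False

        return _T()

    with stage("divergence-tests"):
        used = [cid for cid in sorted(specs) if cid in obs.characters]
        tests = [divergence_test(obs, specs[cid], alpha=cfg.alpha) for cid in used]
        summary = summarize_tests(tests, alpha=cfg.alpha)
        tests_df = tests_to_frame(tests)
        tests_df.to_csv(outdir / "tests.csv", index=False)

    with stage("heritability"):
        h2 = heritability_table(obs, specs, tests)
        h2.to_csv(outdir / "h2.csv", index=False)

    with stage("profiles-and-coding"):
        profiles = {cid: strain_profile(obs, specs[cid]) for cid in used}
        matrix = build_matrix(profiles, tests)
        if matrix.uninformative:
            warnings.append(f"constant coded column(s): {matrix.uninformative}")
        write_nexus_matrix(matrix, outdir / "matrix.nex")
        write_matrix_csv(matrix, outdir / "matrix.csv")

    with stage("parsimony"):
        try:
            tree_set = branch_and_bound(matrix, max_trees=50_000)
            consensus = strict_consensus(tree_set)
            n_mp, mp_score = len(tree_set), tree_set.score
        except ValidationError as exc:
            # degenerate tie structure: stream the consensus instead
            warnings.append(f"tree set not materialized: {exc}")
            log.warning("tree set not materialized: %s", exc)
            tree_set = None
            consensus, mp_score, n_mp = mp_consensus(matrix)
        if cfg.clade_a and cfg.clade_b:
            try:
                consensus = root_between(consensus, cfg.clade_a, cfg.clade_b)
            except ValidationError as exc:
                warnings.append(f"consensus left unrooted: {exc}")
                log.warning("consensus left unrooted: %s", exc)
        write_tree(consensus, outdir / "consensus.nwk")
        with open(outdir / "all-trees.nwk", "w") as fh:
            if tree_set is not None:
                for t in tree_set.trees:
                    fh.write(t.to_newick() + "\n")

    with stage("upgma-bootstrap"):
        scaled = scaled_mean_matrix(profiles, tests)
        dendro = multiscale_bootstrap(
            scaled, n_boot=cfg.n_boot, scales=cfg.scales, seed=cfg.seed,
            restandardize=cfg.restandardize,
        )
        write_tree(dendro.tree, outdir / "dendrogram.nwk")
        dendro.support.to_csv(outdir / "support.csv", index=False)

    import numpy as np
    import scipy

    manifest = {
        "package": {"clonodiverge": __version__, "numpy": np.__version__,
                    "scipy": scipy.__version__, "pandas": pd.__version__},
        "config": {
            "alpha": cfg.alpha, "clade_a": list(cfg.clade_a),
            "clade_b": list(cfg.clade_b), "n_boot": cfg.n_boot,
            "scales": list(cfg.scales), "seed": cfg.seed,
            "restandardize": cfg.restandardize,
        },
        "n_significant": summary.n_significant,
        "parsimony": {"score": mp_score, "n_trees": n_mp},
        "timings_s": timings,
        "warnings": warnings,
        "outputs": {},
    }
    for name in ("tests.csv", "h2.csv", "matrix.nex", "matrix.csv",
                 "consensus.nwk", "all-trees.nwk", "dendrogram.nwk", "support.csv"):
        manifest["outputs"][name] = _digest(outdir / name)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return PipelineResult(
        tests=tests_df, heritability=h2, matrix=matrix, tree_set=tree_set,
        consensus=consensus, dendrogram=dendro.tree, support=dendro.support,
        manifest=manifest, outdir=outdir,
    )
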