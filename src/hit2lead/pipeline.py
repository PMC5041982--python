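"""Orchestrated multi-stage runs: screen -> pharmacophore rank -> QSAR -> crosstab.

A run is configured by a YAML/dict :class:`RunConfig`; stages execute in
the fixed order above, each consuming the previous stage's output files,
and every parameter that affects output is echoed into a JSON manifest
alongside per-stage row counts.  All randomness flows from the config
seed, so a repeated run is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .chem_io import Compound, read_library, write_library
from .crosstab import crosstab, filter_de, load_table3, read_gene_table
from .fingerprints import screen_library
from .pharmacophore import DEFAULT_BIN_EDGES, rank_and_select
from .qsar import cross_validate, fit_pls
from .synthetic import DEFAULT_REFERENCE_SMILES, gen_library, gen_qsar

STAGE_ORDER = ("simulate", "screen", "pharm_rank", "qsar", "crosstab")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stages`` lists the enabled stages (subset of :data:`STAGE_ORDER`);
    ``params`` maps stage name -> parameter dict; ``outdir`` receives all
    stage outputs and the manifest.
    """

    stages: list[str]
    outdir: Path
    seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        stages = list(raw.get("stages", []))
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        cfg = cls(
            stages=[s for s in STAGE_ORDER if s in stages],
            outdir=Path(raw.get("outdir", "pipeline_out")),
            seed=int(raw.get("seed", 0)),
            params={s: dict(raw.get(s, {})) for s in STAGE_ORDER},
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("no stages enabled")
        for stage in self.stages:
            for key in ("library", "reference", "genes", "activities"):
                p = self.params.get(stage, {}).get(key)
                if p is not None and not Path(p).exists():
                    raise ValueError(f"stage {stage}: input file not found: {p}")


def run_pipeline(config: RunConfig | dict | str | Path) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}
    for stage in config.stages:
        params = config.params.get(stage, {})
        try:
            record = _STAGE_FN[stage](config, params, state, outdir)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {"params": dict(params), **record}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _stage_simulate(config, params, state, outdir):
    compounds, truth = gen_library(
        seed=config.seed,
        n_decoys=int(params.get("n_decoys", 100)),
        n_analogs=int(params.get("n_analogs", 5)),
        reference_smiles=params.get("reference_smiles", DEFAULT_REFERENCE_SMILES),
    )
    lib_path = outdir / "library.smi"
    write_library(compounds, lib_path)
    truth.to_csv(outdir / "library_truth.csv", index=False)
    state["library"] = compounds
    state["reference"] = Compound("reference", params.get(
        "reference_smiles", DEFAULT_REFERENCE_SMILES))
    return {"n_compounds": len(compounds), "outputs": ["library.smi", "library_truth.csv"]}


def _resolve_library(config, params, state):
    if "library" in params:
        res = read_library(params["library"])
        return res.compounds
    if "library" in state:
        return state["library"]
    raise ValueError("no library available (no 'library' path and no prior stage output)")


def _resolve_reference(params, state):
    if "reference" in params:
        res = read_library(params["reference"])
        return res.compounds[0]
    if "reference" in state:
        return state["reference"]
    raise ValueError("no reference compound available")


def _stage_screen(config, params, state, outdir):
    library = _resolve_library(config, params, state)
    reference = _resolve_reference(params, state)
    hits = screen_library(
        library,
        reference,
        mode=params.get("mode", "containment"),
        cutoff=float(params.get("cutoff", 1.0)),
    )
    hits.to_csv(outdir / "hits.csv", index=False)
    passing = set(hits.loc[hits["passes"], "compound_id"])
    state["library"] = [c for c in library if c.id in passing]
    state.setdefault("reference", reference)
    return {"n_screened": len(hits), "n_hits": len(passing), "outputs": ["hits.csv"]}


def _stage_pharm_rank(config, params, state, outdir):
    library = _resolve_library(config, params, state)
    reference = _resolve_reference(params, state)
    bins = tuple(params.get("bins", DEFAULT_BIN_EDGES))
    ranked, selected = rank_and_select(
        library,
        reference,
        threshold=float(params.get("threshold", 70.0)),
        bin_edges=bins,
        embed_seed=int(params.get("embed_seed", config.seed or 20160325)),
    )
    ranked.to_csv(outdir / "ranked.csv", index=False)
    state["library"] = [c for c in library if c.id in set(selected)]
    return {"n_ranked": len(ranked), "n_selected": len(selected), "outputs": ["ranked.csv"]}


def _stage_qsar(config, params, state, outdir):
    # QSAR runs on a generated training set (aligned congeneric series with
    # known activities); an external aligned SDF + activity CSV path pair is
    # accepted through the library API in scripts.
    ds = gen_qsar(
        seed=config.seed,
        n_compounds=int(params.get("n_compounds", 40)),
        target_r2=params.get("target_r2"),
        noise_sd=params.get("noise_sd"),
    )
    n_factors = int(params.get("factors", 4))
    model = fit_pls(ds.X, ds.y, n_factors=n_factors)
    cv_params = params.get("cv", {})
    report = cross_validate(
        ds.X,
        ds.y,
        k=int(cv_params.get("k", 5)),
        n_repeats=int(cv_params.get("repeats", 5)),
        n_factors=n_factors,
        seed=int(cv_params.get("seed", 20160325)),
    )
    out = {
        "n_factors": n_factors,
        "r2": model.r2_,
        "rmse": model.rmse_,
        "f": model.f_,
        "q2": report.q2,
        "cv": {"k": report.k, "repeats": report.n_repeats, "seed": report.seed},
    }
    (outdir / "model.json").write_text(json.dumps(out, indent=2) + "\n")
    return {**out, "outputs": ["model.json"]}


def _stage_crosstab(config, params, state, outdir):
    genes = read_gene_table(params["genes"]) if "genes" in params else load_table3()
    down, up = filter_de(
        genes, fdr_max=float(params.get("fdr", 0.01)), fc_min=float(params.get("fc", 1.5))
    )
    summary = crosstab(down, up)
    (outdir / "crosstab.json").write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
    return {"n_down": summary.n_down, "n_up": summary.n_up, "outputs": ["crosstab.json"]}


_STAGE_FN = {
    "simulate": _stage_simulate,
    "screen": _stage_screen,
    "pharm_rank": _stage_pharm_rank,
    "qsar": _stage_qsar,
    "crosstab": _stage_crosstab,
}
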