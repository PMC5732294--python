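"""End-to-end orchestration: graph -> harmonics -> simulate -> analyses.

A single config drives every stage; all stochastic steps take explicit seeds
and the run writes a manifest with checksums and full provenance, so a rerun
with the same config reproduces identical artifacts for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectome, criticality, crossfreq, decomposition, harmonics, spectral, synth
from .errors import ChdError, ConfigError, InputError

DEFAULT_CONFIG = {
    "seed": 1,
    "graph": {"order": 2, "long_edges": 200, "distance_decay": 0.5},
    "harmonics": {"modes": 150},
    "study": {"n_subjects": 6, "t_per_scan": 60, "noise_sd": 0.01},
    "analysis": {
        "levels": 15,
        "bins": 100,
        "partitions": 10,
        "n_perm": 1000,
        "alpha": 0.01,
        "high_band": [0.2, 1.0],
    },
}


class PipelineError(ChdError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config must be a mapping")
    return _merge(DEFAULT_CONFIG, user)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json).

    Partial outputs of a failed run stay quarantined under ``<out>/_work``.
    """
    config = _merge(DEFAULT_CONFIG, config)
    gpath = config["graph"].get("path")
    if gpath is not None and not Path(gpath).exists():
        raise InputError(f"input graph {gpath!r} does not exist")
    out = Path(out_dir)
    work = out / "_work"
    work.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    artifacts: dict[str, Path] = {}
    stage = "init"
    try:
        stage = "build-graph"
        gcfg = config["graph"]
        if "path" in gcfg:
            graph = connectome.load_graph(gcfg["path"])
        else:
            graph = connectome.synth_connectome(
                int(gcfg["order"]),
                int(gcfg["long_edges"]),
                float(gcfg["distance_decay"]),
                seed=seed,
            )
        graph = connectome.prune_isolated(graph)
        connectome.save_graph(graph, work / "graph.mtx")
        artifacts["graph"] = work / "graph.mtx"

        stage = "harmonics"
        modes = config["harmonics"]["modes"]
        basis = harmonics.harmonics_of(graph, modes)
        harmonics.save_basis(basis, work / "basis.h5")
        artifacts["basis"] = work / "basis.h5"

        stage = "simulate"
        scfg = config["study"]
        design = synth.StudyDesign(
            n_subjects=int(scfg["n_subjects"]),
            t_per_scan=int(scfg["t_per_scan"]),
            noise_sd=float(scfg["noise_sd"]),
            test_coupling=synth.CouplingSpec(),
            master_seed=seed,
        )
        records = synth.generate_study(basis, design)

        stage = "decompose"
        coeffs = {}
        for rec in records:
            c = decomposition.decompose(rec["series"], basis)
            c.subject_id = rec["subject"]
            c.condition = rec["condition"]
            coeffs[(rec["subject"], rec["condition"])] = c

        acfg = config["analysis"]

        stage = "spectra"
        energies = {
            key: decomposition.energy(c, basis) for key, c in coeffs.items()
        }
        table = spectral.spectrum_table(energies, n_levels=int(acfg["levels"]))
        table.to_csv(work / "spectra.tsv", sep="\t", index=False)
        artifacts["spectra"] = work / "spectra.tsv"
        contrast = spectral.condition_energy_contrast(
            table,
            (design.baseline_label, design.test_label),
            n_perm=int(acfg["n_perm"]),
            seed=seed,
            alpha=float(acfg["alpha"]),
        )
        contrast.to_csv(work / "spectra_contrast.tsv", sep="\t", index=False)
        artifacts["spectra_contrast"] = work / "spectra_contrast.tsv"

        stage = "crossfreq"
        mats = {
            design.baseline_label: [],
            design.test_label: [],
        }
        for (subj, cond), c in coeffs.items():
            mats[cond].append(crossfreq.crossfreq_matrix(c))
        band = tuple(acfg["high_band"])
        xf = crossfreq.band_contrast(
            mats, band, (design.baseline_label, design.test_label)
        )
        xf["band"] = list(xf["band"])
        (work / "crossfreq_contrast.json").write_text(json.dumps(xf, indent=2))
        artifacts["crossfreq_contrast"] = work / "crossfreq_contrast.json"
        part = crossfreq.partition_means(
            mats[design.test_label][0], p=int(acfg["partitions"])
        )
        np.savetxt(work / "partition_means.tsv", part, delimiter="\t")
        artifacts["partition_means"] = work / "partition_means.tsv"

        stage = "criticality"
        rows = []
        for (subj, cond), c in coeffs.items():
            fits = criticality.fit_scan(
                decomposition.power(c), n_bins=int(acfg["bins"])
            )
            for kind, f in fits.items():
                rows.append(
                    {
                        "subject": subj,
                        "condition": cond,
                        "summary_kind": kind,
                        "beta": f.beta,
                        "intercept": f.intercept,
                        "epsilon": f.epsilon,
                        "n_bins": f.n_bins,
                    }
                )
        fit_table = pd.DataFrame(rows)
        fit_table.to_csv(work / "powerlaw_fits.tsv", sep="\t", index=False)
        artifacts["powerlaw_fits"] = work / "powerlaw_fits.tsv"
        crit = criticality.compare_fits(
            fit_table, (design.baseline_label, design.test_label)
        )
        crit.to_csv(work / "powerlaw_contrast.tsv", sep="\t", index=False)
        artifacts["powerlaw_contrast"] = work / "powerlaw_contrast.tsv"
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, exc) from exc

    # promote artifacts out of the working directory and write the manifest
    final = {}
    for name, path in artifacts.items():
        dest = out / path.name
        dest.write_bytes(path.read_bytes())
        final[name] = dest
    manifest = {
        "config": config,
        "graph_fingerprint": harmonics.graph_fingerprint(graph.adjacency),
        "basis": {"n": basis.n, "m": basis.m, "solver": basis.solver},
        "artifacts": {name: {"path": p.name, "sha256": _sha256(p)} for name, p in final.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for path in artifacts.values():
        path.unlink()
    try:
        work.rmdir()
    except OSError:
        pass
    return manifest
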