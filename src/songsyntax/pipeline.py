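"""End-to-end analysis pipeline: simulate/read -> durations -> dependence
tests -> entropy -> PST cross-validation and fit -> chunking -> PFA ->
similarity, with seeded, configuration-driven runs.

All randomness flows from the single global seed through named per-stage
sub-seeds, so two runs with the same configuration produce byte-identical
JSON reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .annotations import (
    Corpus,
    corpus_to_sequences,
    phrase_records,
    read_annotations,
    records_frame,
    write_annotations,
)
from .contingency import md_report
from .entropy import entropy_profile
from .pfa import count_states, pfa_nll, prune_pfa, pst_to_pfa
from .pst import PSTParams, collapse_internal_nodes, crossvalidate_pst, fit_pst, param_grid, pst_nll
from .simulate import (
    GroundTruthModel,
    SimulationConfig,
    default_model,
    make_ground_truth,
    simulate_contours,
    simulate_corpus,
)
from .spectral import compare_groups

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise PipelineError(
            f"unknown configuration key(s) in {where}: {sorted(unknown)}"
        )


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Either ``input_paths`` (annotation files) or ``simulation`` (a ground
    truth spec for :func:`songsyntax.simulate.make_ground_truth`, or the
    string ``"default"`` for the bundled demo model) must be given.
    """

    out_dir: str = "songsyntax-run"
    seed: int = 0
    input_paths: list[str] = field(default_factory=list)
    dialect: str = "label-track"
    simulation: object = None  # None | "default" | mapping
    n_songs: int = 500
    md: dict = field(default_factory=dict)
    entropy: dict = field(default_factory=dict)
    pst: dict = field(default_factory=dict)
    pfa: dict = field(default_factory=dict)
    spectral: dict = field(default_factory=dict)
    log_level: str = "info"

    ALLOWED = {
        "out_dir", "seed", "input_paths", "dialect", "simulation",
        "n_songs", "md", "entropy", "pst", "pfa", "spectral", "log_level",
    }

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        _check_keys(dict(mapping), cls.ALLOWED, "run config")
        cfg = cls(**mapping)
        _check_keys(
            cfg.md, {"tests", "n_randomizations", "alpha", "min_count"},
            "md",
        )
        _check_keys(cfg.entropy, {"n_max", "n_shuffles"}, "entropy")
        _check_keys(
            cfg.pst,
            {"p_min_grid", "r", "gamma_min", "alpha", "l_max", "k_folds",
             "repeats", "selection"},
            "pst",
        )
        _check_keys(cfg.pfa, {"prune_threshold"}, "pfa")
        _check_keys(
            cfg.spectral, {"labels", "n_renditions", "group_shift"},
            "spectral",
        )
        if not cfg.input_paths and cfg.simulation is None:
            raise PipelineError(
                "config needs either input_paths or a simulation spec"
            )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


def _stage_seed(root_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _dump(obj, path: Path) -> None:
    path.write_text(
        json.dumps(obj, indent=1, sort_keys=True, ensure_ascii=False),
        encoding="utf-8",
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage; returns the report dict (also written to
    ``<out_dir>/report.json`` along with per-stage artifacts)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "songsyntax_version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    k: v
                    for k, v in dataclasses.asdict(config).items()
                    if k != "out_dir"  # identical runs hash alike anywhere
                },
                sort_keys=True,
                default=str,
            ).encode()
        ).hexdigest()[:16],
        "stages": {},
    }

    def fail(stage: str, exc: Exception):
        _dump(report, out / "report.json")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- corpus ----------------------------------------------------------
    model: GroundTruthModel | None = None
    try:
        if config.input_paths:
            corpus = read_annotations(config.input_paths, config.dialect)
        else:
            if config.simulation == "default":
                model = default_model(seed=_stage_seed(config.seed, "model"))
            elif isinstance(config.simulation, GroundTruthModel):
                model = config.simulation
            else:
                model = make_ground_truth(config.simulation)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corpus = simulate_corpus(
                    model,
                    SimulationConfig(
                        n_songs=config.n_songs,
                        seed=_stage_seed(config.seed, "corpus"),
                    ),
                )
            write_annotations(
                corpus, out / "corpus.tsv", dialect="combined-tsv"
            )
        records = phrase_records(corpus)
        frame = records_frame(records)
        report["stages"]["corpus"] = {
            "n_songs": len(corpus),
            "n_phrases": corpus.n_phrases,
            "alphabet_size": len(corpus.alphabet),
        }
    except Exception as exc:  # noqa: BLE001
        fail("corpus", exc)

    # ---- duration statistics --------------------------------------------
    try:
        durs = frame["duration"]
        per_type = (
            frame.groupby("label")["duration"]
            .agg(["count", "mean", "median", "std"])
            .reset_index()
        )
        per_type.to_csv(out / "durations_by_type.tsv", sep="\t", index=False)
        report["stages"]["durations"] = {
            "median_s": float(durs.median()),
            "mean_s": float(durs.mean()),
            "q05_s": float(durs.quantile(0.05)),
            "q95_s": float(durs.quantile(0.95)),
        }
    except Exception as exc:  # noqa: BLE001
        fail("durations", exc)

    # ---- mutual dependence ----------------------------------------------
    try:
        mdcfg = dict(config.md)
        df = md_report(
            corpus,
            tests=tuple(
                mdcfg.get(
                    "tests",
                    ("MD(dur,path_in)", "MD(dur,path_out)",
                     "MD(path_in,path_out)"),
                )
            ),
            n_randomizations=int(mdcfg.get("n_randomizations", 20_000)),
            alpha=float(mdcfg.get("alpha", 0.001)),
            min_count=int(mdcfg.get("min_count", 10)),
            seed=_stage_seed(config.seed, "md"),
        )
        df.to_csv(out / "md_results.tsv", sep="\t", index=False)
        ok = df[df["status"] == "ok"]
        report["stages"]["mutual_dependence"] = {
            "n_tests_run": int(df.attrs["n_tests_run"]),
            "alpha": df.attrs["alpha"],
            "n_significant": int(ok["significant"].sum()),
            "fraction_significant_by_test": {
                t: float(sub["significant"].mean()) if len(sub) else None
                for t, sub in ok.groupby("test")
            },
        }
    except Exception as exc:  # noqa: BLE001
        fail("mutual_dependence", exc)

    # ---- block entropy ---------------------------------------------------
    try:
        ecfg = dict(config.entropy)
        seqs = corpus_to_sequences(corpus)
        profile = entropy_profile(
            seqs,
            n_max=int(ecfg.get("n_max", 5)),
            n_shuffles=int(ecfg.get("n_shuffles", 50)),
            seed=_stage_seed(config.seed, "entropy"),
        )
        profile.frame().to_csv(
            out / "entropy_curves.tsv", sep="\t", index=False
        )
        report["stages"]["entropy"] = {
            "n_max": int(profile.data.n[-1]),
            "H_data": [float(h) for h in profile.data.H],
            "H_first_order_mean": [float(h) for h in profile.first_order.H],
            "H_zero_order_mean": [float(h) for h in profile.zero_order.H],
            "H_max": [float(h) for h in profile.max_entropy.H],
        }
    except Exception as exc:  # noqa: BLE001
        fail("entropy", exc)

    # ---- PST: cross-validate, fit, chunk --------------------------------
    try:
        pcfg = dict(config.pst)
        base = PSTParams(
            p_min=0.007,
            r=float(pcfg.get("r", 1.55)),
            gamma_min=float(pcfg.get("gamma_min", 0.001)),
            alpha=float(pcfg.get("alpha", 0.12)),
            l_max=int(pcfg.get("l_max", 8)),
        )
        grid = param_grid(
            p_min=tuple(
                pcfg.get("p_min_grid", (0.05, 0.02, 0.007, 0.003))
            ),
            r=(base.r,),
            gamma_min=(base.gamma_min,),
            alpha=(base.alpha,),
            l_max=(base.l_max,),
        )
        cv = crossvalidate_pst(
            seqs,
            grid,
            k_folds=int(pcfg.get("k_folds", 10)),
            repeats=int(pcfg.get("repeats", 3)),
            seed=_stage_seed(config.seed, "cv"),
            selection=pcfg.get("selection", "min"),
        )
        cv.by_params().to_csv(out / "cv_report.tsv", sep="\t", index=False)
        tree = fit_pst(seqs, cv.selected)
        (out / "pst.json").write_text(tree.to_json(), encoding="utf-8")
        (out / "pst.dot").write_text(tree.to_dot(), encoding="utf-8")
        chunk = collapse_internal_nodes(tree, seqs)
        report["stages"]["pst"] = {
            "selected_p_min": cv.selected.p_min,
            "n_nodes": len(tree),
            "max_depth": tree.depth,
            "train_nll_bits_per_phrase": pst_nll(tree, seqs),
            "chunks": chunk.chunk_symbols,
            "depth_after_chunking": chunk.depth_after,
            "chunk_percent_nll_change": chunk.percent_nll_change,
        }
    except Exception as exc:  # noqa: BLE001
        fail("pst", exc)

    # ---- PFA -------------------------------------------------------------
    try:
        fcfg = dict(config.pfa)
        pfa = pst_to_pfa(tree)
        (out / "pfa.json").write_text(pfa.to_json(), encoding="utf-8")
        thr = float(fcfg.get("prune_threshold", 0.2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pruned = prune_pfa(pfa, thr)
        (out / "pfa.dot").write_text(pruned.to_dot(), encoding="utf-8")
        summary = count_states(pfa, threshold=thr)
        report["stages"]["pfa"] = {
            "n_states": summary.n_states,
            "n_symbols": summary.n_symbols,
            "n_edges_above_threshold": summary.n_edges,
            "prune_threshold": thr,
            "n_edges_hidden": pruned.n_hidden,
            "nll_identity_gap_bits": abs(
                pst_nll(tree, seqs) - pfa_nll(pfa, seqs)
            ),
        }
    except Exception as exc:  # noqa: BLE001
        fail("pfa", exc)

    # ---- spectral similarity (synthetic corpora only) --------------------
    try:
        if model is not None:
            scfg = dict(config.spectral)
            labels = list(
                scfg.get("labels", sorted(corpus.alphabet)[:2])
            )
            n = int(scfg.get("n_renditions", 100))
            shift = tuple(scfg.get("group_shift", (0.0, 10.0)))
            sseed = _stage_seed(config.seed, "spectral")
            spectral_out = {}
            for lab in labels:
                a = simulate_contours(
                    model, lab, n, seed=sseed, group="ref"
                )
                b = simulate_contours(
                    model, lab, n, seed=sseed + 1, group="same"
                )
                c = simulate_contours(
                    model, lab, n, group_shift=shift, seed=sseed + 2,
                    group="shifted",
                )
                res = compare_groups(
                    {"ref": a, "same": b, "shifted": c}, "ref"
                )
                i = res.group_labels.index("ref")
                spectral_out[lab] = {
                    "dprime_same": float(
                        res.dprime_table[i][
                            res.group_labels.index("same")
                        ]
                    ),
                    "dprime_shifted": float(
                        res.dprime_table[i][
                            res.group_labels.index("shifted")
                        ]
                    ),
                    "ks_p_same": res.ks_p["same"],
                    "ks_p_shifted": res.ks_p["shifted"],
                }
                sseed += 10
            report["stages"]["spectral"] = spectral_out
        else:
            report["stages"]["spectral"] = "skipped (no contour source)"
    except Exception as exc:  # noqa: BLE001
        fail("spectral", exc)

    _dump(report, out / "report.json")
    return report
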