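"""Session orchestration: features -> models -> evaluation -> report tables.

A session manifest (JSON) names the input data (or synthetic-generation
parameters), the cross-validation configuration, and the feature-set ladder
to evaluate (by default: lfp; kin; kin+lfp; kin+hist; kin+hist+lfp).  The
report bundle contains per-unit predictive power for each ladder member with
the block-shuffle chance level, the nested-model comparisons, and a
per-feature breakdown (one small model per LFP feature per band).  Every
number is reproducible from the manifest: all randomness derives from the
manifest seed and the configuration hash is recorded in the outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BinnedSpikeTrain, FeatureBlock
from .evaluation import (
    CVConfig,
    chance_population,
    compare_feature_sets,
    evaluate_population,
    roc_hull_pp,
)
from .history import raised_cosine_basis, history_columns
from .lfp import DEFAULT_BANDS, EDGE_MARGIN_MS, BandDefinition, lfp_feature_blocks
from .kinematics import pathlet_features, smooth_velocity
from .ppglm import assemble_design, fit_ppglm, conditional_intensity
from .synthetic import (
    SyntheticSession,
    generate_session,
    load_session,
    population_truths,
)

DEFAULT_LADDERS = ("lfp", "kin", "kin+lfp", "kin+hist", "kin+hist+lfp")
DEFAULT_COMPARISONS = (
    ("kin", "kin+lfp"),
    ("kin", "kin+hist"),
    ("kin+hist", "kin+hist+lfp"),
)


@dataclass
class SessionBlocks:
    """Cropped per-session feature blocks on the usable model grid."""

    lfp: FeatureBlock
    kin: FeatureBlock
    hist: list  # per-unit FeatureBlock
    Y: list  # per-unit BinnedSpikeTrain (cropped)
    usable: slice


def build_blocks(
    session: SyntheticSession,
    bands=DEFAULT_BANDS,
    *,
    margin_ms: int = EDGE_MARGIN_MS,
) -> SessionBlocks:
    """Extract LFP, pathlet and history blocks, cropped to the usable window.

    The first ``margin_ms`` and last ``margin_ms`` model bins are discarded:
    they are dominated by band-filter/Hilbert transients and fall inside the
    pathlet (-100, +300) ms margins.
    """
    T = session.spikes[0].n_bins
    usable = slice(margin_ms, T - margin_ms)
    lfp_block = lfp_feature_blocks(session.lfp[0], tuple(bands)).sliced(usable)
    sm = smooth_velocity(session.kinematics)
    times = np.arange(T)[usable]
    kin_block = pathlet_features(session.kinematics, times, smoothed=sm)
    basis = raised_cosine_basis()
    hist = [history_columns(sp, basis).sliced(usable) for sp in session.spikes]
    Y = [
        BinnedSpikeTrain(sp.values[usable], t0_ms=float(margin_ms),
                         label=sp.label)
        for sp in session.spikes
    ]
    return SessionBlocks(lfp=lfp_block, kin=kin_block, hist=hist, Y=Y,
                         usable=usable)


def ladder_blocks(sb: SessionBlocks, ladder: str, unit: int) -> list[FeatureBlock]:
    """Feature blocks for a '+'-joined ladder name such as 'kin+hist+lfp'."""
    out = []
    for part in ladder.split("+"):
        if part == "lfp":
            out.append(sb.lfp)
        elif part == "kin":
            out.append(sb.kin)
        elif part == "hist":
            out.append(sb.hist[unit])
        else:
            raise ValueError(f"unknown ladder component {part!r}")
    return out


#: per-feature model definitions (Eq-style single-feature fits per band)
_PER_FEATURE = {
    "amplitude": ("amp",),
    "analytic": ("re", "im"),
    "phase": ("cosph", "sinph"),
}


def per_feature_pp(
    sb: SessionBlocks,
    unit: int,
    config: CVConfig,
    bands=DEFAULT_BANDS,
    *,
    alpha: float = 0.0,
) -> pd.DataFrame:
    """Predictive power of one small model per LFP feature per band.

    Phase (cos/sin pair) and analytic signal (Re/Im pair) each count as one
    model; broad bands have no phase model.  Ten-fold CV with a fixed alpha
    (the models have at most two covariates, so no penalty selection is
    needed); reports pooled PP.
    """
    y = sb.Y[unit].values.astype(float)
    T = y.size
    folds = np.array_split(np.arange(T), config.outer_folds)
    rows = []
    labels = list(sb.lfp.labels)
    for band in bands:
        for fname, suffixes in _PER_FEATURE.items():
            cols = [f"{band.name}_{sfx}" for sfx in suffixes]
            if not all(c in labels for c in cols):
                continue  # broad bands carry no phase features
            sel = [labels.index(c) for c in cols]
            sub = sb.lfp.values[:, sel]
            scores = np.empty(T)
            for i, test_idx in enumerate(folds):
                train_idx = np.concatenate(
                    [f for j, f in enumerate(folds) if j != i]
                )
                Xtr = assemble_design(
                    [FeatureBlock(sub[train_idx], cols, "lfp")]
                )
                model = fit_ppglm(Xtr, y[train_idx], alpha)
                Xte = assemble_design(
                    [FeatureBlock(sub[test_idx], cols, "lfp")], stats_from=Xtr
                )
                scores[test_idx] = np.log(conditional_intensity(model, Xte))
            rows.append(
                {
                    "unit": sb.Y[unit].label,
                    "band": band.name,
                    "feature": fname,
                    "pp": roc_hull_pp(scores, y),
                }
            )
    return pd.DataFrame(rows)


def _load_manifest(manifest) -> tuple[dict, Path]:
    if isinstance(manifest, (str, Path)):
        path = Path(manifest)
        if not path.exists():
            raise FileNotFoundError(f"manifest not found: {path}")
        return json.loads(path.read_text()), path.parent
    return dict(manifest), Path.cwd()


def run_session(manifest, output_dir=None) -> dict:
    """Run the full per-session analysis described by a manifest.

    Returns the report dict and writes ``pp_by_unit.csv``,
    ``comparisons.json``, ``per_feature_pp.csv`` and ``log.txt`` to the
    output directory.
    """
    spec, base = _load_manifest(manifest)
    seed = int(spec.get("seed", 0))
    out = Path(output_dir or spec.get("output_dir", "spikefield_out"))
    if not out.is_absolute():
        out = base / out
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    cfg_hash = hashlib.sha256(
        json.dumps(spec, sort_keys=True).encode()
    ).hexdigest()[:16]
    log(f"config_hash={cfg_hash} seed={seed}")

    # --- load or generate the session -----------------------------------
    if "session_dir" in spec:
        sdir = Path(spec["session_dir"])
        if not sdir.is_absolute():
            sdir = base / sdir
        log(f"stage=load session_dir={sdir}")
        session = load_session(sdir)
    elif "synthetic" in spec:
        syn = dict(spec["synthetic"])
        n_units = int(syn.get("n_units", 2))
        duration = float(syn.get("duration_s", 120.0))
        coupling = float(syn.get("coupling", 1.0))
        log(
            f"stage=generate n_units={n_units} duration_s={duration} "
            f"coupling={coupling}"
        )
        truths = population_truths(seed, n_units, coupling=coupling)
        session = generate_session(truths, duration)
    else:
        raise ValueError("manifest needs either 'session_dir' or 'synthetic'")

    bands = tuple(
        BandDefinition(*b) for b in spec.get("bands", [])
    ) or DEFAULT_BANDS
    cv_spec = dict(spec.get("cv", {}))
    cv_spec.setdefault("seed", seed)
    config = CVConfig(**cv_spec)
    ladders = tuple(spec.get("ladders", DEFAULT_LADDERS))
    comparisons = tuple(
        tuple(c) for c in spec.get("comparisons", DEFAULT_COMPARISONS)
    )
    comparisons = tuple(
        (b, e) for b, e in comparisons if b in ladders and e in ladders
    )

    log("stage=features")
    sb = build_blocks(session, bands)

    # --- per-unit model ladder ------------------------------------------
    log(f"stage=fit ladders={','.join(ladders)}")
    results = evaluate_population(
        sb.kin, sb.lfp, sb.hist, sb.Y, config, ladders=ladders
    )
    chance: list[float] = []
    if spec.get("chance", True) and "lfp" in ladders:
        alphas = [
            max(float(np.median(r.selected_alphas)), 1e-6)
            for r in results["lfp"]
        ]
        thr, _ = chance_population(
            [sb.lfp], sb.Y, config, config.n_perm, alphas=alphas
        )
        for u, r in enumerate(results["lfp"]):
            r.chance_pp_95 = float(thr[u])
            log(f"stage=chance unit={r.unit} pp95={thr[u]:.4f}")
        chance = [float(t) for t in thr]

    # --- tables ----------------------------------------------------------
    table = pd.DataFrame(
        {
            "unit": [y.label for y in sb.Y],
            **{
                lad: [r.pp_pooled for r in results[lad]] for lad in ladders
            },
        }
    )
    if chance:
        table["chance_lfp_95"] = chance
    table.to_csv(out / "pp_by_unit.csv", index=False)

    comp_out = []
    if len(sb.Y) >= 6:
        for b, e in comparisons:
            cr = compare_feature_sets(results, b, e, n_tests=len(comparisons))
            comp_out.append(
                {
                    "base": cr.base,
                    "extended": cr.extended,
                    "mean_delta": cr.mean_delta,
                    "median_delta": cr.median_delta,
                    "p_value": cr.p_value,
                    "n_tests_bonferroni": cr.n_tests_bonferroni,
                    "significant": cr.significant,
                    "delta_pp_per_unit": cr.delta_pp_per_unit.tolist(),
                }
            )
    else:
        log("stage=compare skipped (fewer than 6 units)")

    report = {
        "seed": seed,
        "config_hash": cfg_hash,
        "n_units": len(sb.Y),
        "ladders": list(ladders),
        "pp_by_unit": table.to_dict(orient="list"),
        "comparisons": comp_out,
    }
    (out / "comparisons.json").write_text(json.dumps(report, indent=2))

    if spec.get("per_feature", True):
        log("stage=per_feature")
        pf = pd.concat(
            [per_feature_pp(sb, u, config, bands) for u in range(len(sb.Y))],
            ignore_index=True,
        )
        pf.to_csv(out / "per_feature_pp.csv", index=False)

    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return report
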