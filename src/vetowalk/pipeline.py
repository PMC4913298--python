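"""Experiment orchestration: seeded end-to-end runs and qualitative checks.

``run_experiment`` composes the chain builders, trial generators, SVM
pipeline and analytic MI into a result bundle on disk (CSV tables + JSON
sidecars + a run log).  ``compare_figures`` re-reads a bundle and checks
the qualitative claims (100% at t=0, complete-graph plateau, accuracy and
MI ordering by size, Bayes bound, relaxation-time ordering).
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import chains as ch
from . import classify as cl
from . import info as it
from . import trials as tr

logger = logging.getLogger("vetowalk")

PROFILES = {
    "desk": {"k": 50, "M": 20, "N": 60},
    "paper": {"k": 500, "M": 50, "N": 100},  # nominal: the source k, guessed M/N
}

__all__ = ["ExperimentConfig", "PROFILES", "run_experiment", "compare_figures"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of a full experiment run."""

    topology: str = "line"
    n: Sequence[int] = (5, 10)
    N: int = 60
    M: int = 20
    k: int = 50
    p_switch: float = 0.001
    seed: int = 0
    mode: str = "reversed"
    svm_penalty: float = 1.0
    custom_matrix: Optional[str] = None  # CSV path when topology == "custom"
    analyses: Sequence[str] = ("accuracy", "mi", "spectra", "avg_position")

    def __post_init__(self) -> None:
        ns = tuple(int(v) for v in (self.n if not isinstance(self.n, int) else [self.n]))
        object.__setattr__(self, "n", ns)
        object.__setattr__(self, "analyses", tuple(self.analyses))
        if self.topology not in ("line", "complete", "custom"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology == "custom" and not self.custom_matrix:
            raise ValueError("custom topology requires custom_matrix")
        bad = set(self.analyses) - {"accuracy", "mi", "spectra", "avg_position"}
        if bad:
            raise ValueError(f"unknown analyses: {sorted(bad)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n"] = list(self.n)
        d["analyses"] = list(self.analyses)
        return d

    @classmethod
    def from_dict(cls, doc: dict) -> "ExperimentConfig":
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def build_chain(self, n: int) -> ch.MarkovChain:
        if self.topology == "line":
            return ch.build_line_chain(n)
        if self.topology == "complete":
            return ch.build_complete_graph_chain(n)
        return ch.MarkovChain.from_csv(self.custom_matrix)


def _run_one(config: ExperimentConfig, n: int, outdir: Path) -> dict:
    chain = config.build_chain(n)
    prefix = f"{config.topology}_n{chain.n_interior}"
    entry: dict = {"n": chain.n_interior, "prefix": prefix}

    t0 = time.perf_counter()
    gen = tr.GeneratorConfig(
        chain=chain, N=config.N, M=config.M, k=config.k,
        p_switch=config.p_switch, seed=config.seed, mode=config.mode,
    )
    trials = tr.generate_trials(gen)
    trials.to_csv(outdir / f"{prefix}_trials.csv")
    entry["trials"] = f"{prefix}_trials.csv"
    logger.info("simulate %s seed=%d n=%d: %.2fs", config.topology,
                config.seed, n, time.perf_counter() - t0)

    if "accuracy" in config.analyses:
        t0 = time.perf_counter()
        curve = cl.accuracy_timecourse(trials, svm_penalty=config.svm_penalty)
        curve.to_csv(outdir / f"{prefix}_accuracy.csv",
                     outdir / f"{prefix}_accuracy_grand.csv")
        entry["accuracy"] = f"{prefix}_accuracy.csv"
        entry["accuracy_grand"] = f"{prefix}_accuracy_grand.csv"
        logger.info("classify n=%d: %.2fs", n, time.perf_counter() - t0)

    if "mi" in config.analyses:
        it.mi_timecourse(chain, config.N).to_csv(outdir / f"{prefix}_mi.csv")
        entry["mi"] = f"{prefix}_mi.csv"

    if "spectra" in config.analyses:
        summary = ch.spectral_summary(chain)
        (outdir / f"{prefix}_spectra.json").write_text(
            json.dumps(summary.to_dict(), indent=1))
        entry["spectra"] = f"{prefix}_spectra.json"

    if "avg_position" in config.analyses:
        tr.average_position_curve(trials).to_csv(outdir / f"{prefix}_avg_position.csv")
        entry["avg_position"] = f"{prefix}_avg_position.csv"
    return entry


def run_experiment(config: ExperimentConfig, outdir: Union[str, Path]) -> Path:
    """Run all configured analyses for every ``n``; returns the bundle dir.

    Deterministic given the seed.  On failure, partially written outputs
    are removed (only files created by this run).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not outdir.is_dir():
        raise ValueError(f"cannot create output directory {outdir}")
    created_before = set(p.name for p in outdir.iterdir())
    try:
        entries = [_run_one(config, n, outdir) for n in config.n]
        manifest = {"config": config.to_dict(), "runs": entries,
                    "created": time.strftime("%Y-%m-%dT%H:%M:%S")}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        config.to_yaml(outdir / "config.yaml")
    except Exception:
        for p in outdir.iterdir():
            if p.name not in created_before:
                p.unlink() if p.is_file() else shutil.rmtree(p)
        raise
    return outdir


def _load_grand(outdir: Path, name: str):
    import pandas as pd

    path = outdir / name
    if not path.exists():
        return None
    return pd.read_csv(path)


def compare_figures(outdir: Union[str, Path]) -> dict:
    """Qualitative pass/fail report for a completed bundle.

    Returns ``{"checks": [...], "n_failed": int, "n_skipped": int}``;
    missing bundle components mark the affected checks as skipped.
    """
    outdir = Path(outdir)
    checks: list[dict] = []

    def add(name: str, status: str, detail: str = "") -> None:
        checks.append({"name": name, "status": status, "detail": detail})

    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        add("manifest", "skipped", "manifest.json missing")
        return {"checks": checks, "n_failed": 0, "n_skipped": 1}
    manifest = json.loads(manifest_path.read_text())
    config = ExperimentConfig.from_dict(manifest["config"])
    runs = {e["n"]: e for e in manifest["runs"]}

    grand = {}
    for n, entry in runs.items():
        df = _load_grand(outdir, entry.get("accuracy_grand", ""))
        if df is not None:
            grand[n] = df

    # accuracy at the locking point
    for n, df in sorted(grand.items()):
        a0 = float(df.loc[df["t"] == 0, "accuracy"].iloc[0])
        if abs(a0 - 100.0) < 1e-9:
            add(f"accuracy_t0_n{n}", "pass", f"accuracy(t=0)={a0:.1f}")
        else:
            add(f"accuracy_t0_n{n}", "fail", f"accuracy(t=0)={a0:.1f}, expected 100")
    if not grand:
        add("accuracy_t0", "skipped", "no accuracy tables in bundle")

    if config.topology == "complete":
        for n, df in sorted(grand.items()):
            pre = df.loc[df["t"] <= -1, "accuracy"]
            avg_dev = float(abs(pre.mean() - 50.0))
            per = _load_grand(outdir, runs[n].get("accuracy", ""))
            detail = f"|mean_t a_t - 50| = {avg_dev:.2f} for t<=-1"
            ok = avg_dev <= 2.0
            if per is not None:
                # per-t deviations judged against their own Monte-Carlo error
                wide = per.pivot(index="participant", columns="t", values="accuracy")
                wide = wide.loc[:, wide.columns <= -1]
                se = wide.std(axis=0, ddof=1) / np.sqrt(wide.shape[0])
                z = float(((wide.mean(axis=0) - 50.0).abs() / se).max())
                ok = ok and z <= 4.0
                detail += f"; max per-t deviation = {z:.2f} SE"
            add(f"plateau_50_n{n}", "pass" if ok else "fail", detail)
    elif config.topology == "line" and len(grand) >= 2:
        ns = sorted(grand)
        lo, hi = ns[0], ns[-1]
        mean_lo = float(grand[lo].loc[grand[lo]["t"] < 0, "accuracy"].mean())
        mean_hi = float(grand[hi].loc[grand[hi]["t"] < 0, "accuracy"].mean())
        status = "pass" if mean_hi >= mean_lo else "fail"
        add("accuracy_ordering", status,
            f"mean pre-event accuracy n={hi}: {mean_hi:.2f} >= n={lo}: {mean_lo:.2f}")

    # Bayes bound on the grand mean
    for n, df in sorted(grand.items()):
        per = _load_grand(outdir, runs[n].get("accuracy", ""))
        if per is None:
            add(f"bayes_bound_n{n}", "skipped", "per-participant accuracy missing")
            continue
        chain = config.build_chain(n)
        bayes = cl.bayes_accuracy_curve(chain, config.N)
        wide = per.pivot(index="participant", columns="t", values="accuracy")
        wide = wide.reindex(columns=np.arange(-(config.N - 1), 1))
        se = wide.std(axis=0, ddof=1).to_numpy() / np.sqrt(wide.shape[0])
        excess = wide.mean(axis=0).to_numpy() - (bayes + 3.0 * se)
        worst = float(excess.max())
        add(f"bayes_bound_n{n}", "pass" if worst <= 1e-9 else "fail",
            f"max(grand - bayes - 3SE) = {worst:.3f}")

    # MI ordering by size
    mi = {}
    for n, entry in runs.items():
        df = _load_grand(outdir, entry.get("mi", ""))
        if df is not None:
            mi[n] = df
    if config.topology == "line" and len(mi) >= 2:
        ns = sorted(mi)
        lo, hi = ns[0], ns[-1]
        a = mi[lo].set_index("t")["I0_bits"]
        b = mi[hi].set_index("t")["I0_bits"]
        ok = bool((b[b.index <= -1] >= a[a.index <= -1] - 1e-12).all())
        add("mi_ordering", "pass" if ok else "fail",
            f"I0(n={hi}) >= I0(n={lo}) at all t <= -1: {ok}")
    elif config.topology == "complete" and mi:
        n = sorted(mi)[0]
        df = mi[n]
        tail = df.loc[df["t"] <= -1, "I0_bits"].abs().max()
        at0 = float(df.loc[df["t"] == 0, "I0_bits"].iloc[0])
        ok = tail < 1e-12 and abs(at0 - 1.0) < 1e-12
        add("mi_complete", "pass" if ok else "fail",
            f"I0(0)={at0}, max|I0(t<=-1)|={tail:.2e}")

    # relaxation-time ordering
    taus = {}
    for n, entry in runs.items():
        path = outdir / entry.get("spectra", "@missing")
        if path.exists():
            taus[n] = json.loads(path.read_text())["relaxation_time"]
    if config.topology == "line" and len(taus) >= 2:
        ns = sorted(taus)
        ok = all(taus[a] < taus[b] for a, b in zip(ns, ns[1:]))
        add("tau_ordering", "pass" if ok else "fail",
            "; ".join(f"tau1(n={n})={taus[n]:.2f}" for n in ns))
    elif config.topology == "complete" and taus:
        n = sorted(taus)[0]
        ok = abs(taus[n]) < 1e-9
        add("tau_complete_zero", "pass" if ok else "fail", f"tau1={taus[n]:.2e}")

    n_failed = sum(c["status"] == "fail" for c in checks)
    n_skipped = sum(c["status"] == "skipped" for c in checks)
    return {"checks": checks, "n_failed": n_failed, "n_skipped": n_skipped}
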