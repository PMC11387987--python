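"""End-to-end orchestration: feature extraction, screening, evaluation runs.

This is the library backend of the command-line interface.  A
:class:`RunConfig` describes a full run (simulate or load a cohort, extract
feature families, screen features, evaluate a classifier under one of the
cross-validation protocols, optionally sweep noise levels); its schema is
validated strictly before any computation and unknown keys are rejected.
One top-level seed derives all stage seeds through ``numpy`` seed sequences,
so any stage can be re-run in isolation reproducibly.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .baseline_features import (
    descriptive_features,
    histogram_poincare_features,
    percentage_index,
    tone_entropy,
    wavelet_multiscale_features,
)
from .evaluation import (
    ClassifierSpec,
    EvalReport,
    cv_leave_one_fold_out,
    cv_leave_one_sample_out,
    cv_stratified_kfold,
    noise_sweep,
    screen_features,
)
from .mfc_core import (
    Cohort,
    FeatureTable,
    FormatError,
    MFCSeries,
    normalize_series,
    read_cohort,
    write_cohort,
    write_feature_table,
)
from .spectral import STFTConfig, cohort_mean_spectra, spectral_features
from .synthetic import CohortConfig, default_config, generate_cohort

__all__ = [
    "FAMILIES",
    "RunConfig",
    "extract_feature_table",
    "series_features",
    "run_pipeline",
    "stage_seed",
]

FAMILIES = (
    "spectral",
    "descriptive",
    "histogram_poincare",
    "tone_entropy",
    "wavelet",
)


def stage_seed(seed: int, stage: int) -> int:
    """Derive a stage seed (< 2**31) from the top-level seed."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def _prepare(s: MFCSeries, family: str) -> MFCSeries:
    """Per-family normalization policy for raw input series.

    Already-normalized series pass through.  Raw series are minmax-normalized
    except for tone-entropy, which uses max normalization so the percentage
    index stays defined (minmax introduces an exact zero).
    """
    if s.normalized:
        return s
    method = "max" if family == "tone_entropy" else "minmax"
    return normalize_series(s, method)


def series_features(
    s: MFCSeries,
    family: str,
    stft_cfg: STFTConfig | None = None,
    n_spectral: int = 3,
) -> dict[str, float]:
    """Extract one family's feature vector from one series."""
    s = _prepare(s, family)
    if family == "spectral":
        return spectral_features(s, stft_cfg, n_features=n_spectral)
    if family == "descriptive":
        return descriptive_features(s)
    if family == "histogram_poincare":
        return histogram_poincare_features(s)
    if family == "tone_entropy":
        tone, entropy = tone_entropy(percentage_index(s))
        return {"tone": tone, "entropy": entropy}
    if family == "wavelet":
        return wavelet_multiscale_features(s)
    raise FormatError(f"unknown feature family {family!r}; choose from {FAMILIES}")


def extractor_for(
    family: str, stft_cfg: STFTConfig | None = None, n_spectral: int = 3
) -> Callable[[MFCSeries], dict[str, float]]:
    """A single-series feature extractor bound to one family/configuration."""
    return lambda s: series_features(s, family, stft_cfg, n_spectral)


def extract_feature_table(
    cohort: Cohort,
    family: str = "spectral",
    stft_cfg: STFTConfig | None = None,
    n_spectral: int = 3,
) -> FeatureTable:
    """Per-subject feature table for one family."""
    fn = extractor_for(family, stft_cfg, n_spectral)
    return FeatureTable.from_records(
        [(s.subject_id, s.label, fn(s)) for s in cohort]
    )


_KNOWN_KEYS = {
    "io": {"cohort_csv", "out_dir"},
    "simulate": {"n_improved", "n_unimproved", "n_strides"},
    "stft": {"n_segments", "overlap", "window", "nfft"},
    "features": {"families", "n_spectral"},
    "cv": {"scheme", "n_per_class", "n_repeats", "k"},
    "classifier": {"kind", "params"},
    "noise": {"levels"},
}


@dataclass
class RunConfig:
    """Validated full-pipeline configuration."""

    out_dir: str
    cohort_csv: str | None = None
    simulate: dict | None = None
    stft: STFTConfig = field(default_factory=STFTConfig)
    families: tuple[str, ...] = ("spectral",)
    n_spectral: int = 3
    cv_scheme: str = "loso"
    cv_params: dict = field(default_factory=dict)
    classifier: ClassifierSpec = field(default_factory=lambda: ClassifierSpec("svm"))
    noise_levels: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for fam in self.families:
            if fam not in FAMILIES:
                raise FormatError(f"unknown feature family {fam!r}")
        if self.cv_scheme not in ("loso", "lofo", "stratified5"):
            raise FormatError(f"unknown cv scheme {self.cv_scheme!r}")
        if self.cohort_csv is None and self.simulate is None:
            raise FormatError("config must provide io.cohort_csv or a simulate block")

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "RunConfig":
        unknown = set(raw) - set(_KNOWN_KEYS) - {"seed"}
        if unknown:
            raise FormatError(f"unknown config sections: {sorted(unknown)}")
        for section, keys in _KNOWN_KEYS.items():
            if section in raw and raw[section] is not None:
                extra = set(raw[section]) - keys
                if extra:
                    raise FormatError(
                        f"unknown keys in {section!r}: {sorted(extra)}"
                    )
        io = raw.get("io", {}) or {}
        if "out_dir" not in io:
            raise FormatError("config requires io.out_dir")
        stft_raw = raw.get("stft", {}) or {}
        stft = STFTConfig(
            n_segments=stft_raw.get("n_segments", 8),
            overlap=stft_raw.get("overlap", 0.5),
            window=stft_raw.get("window", "hamming"),
            nfft=stft_raw.get("nfft", 256),
        )
        feat = raw.get("features", {}) or {}
        clf = raw.get("classifier", {}) or {}
        cv = dict(raw.get("cv", {}) or {})
        noise = raw.get("noise", {}) or {}
        return cls(
            out_dir=str(io["out_dir"]),
            cohort_csv=io.get("cohort_csv"),
            simulate=raw.get("simulate"),
            stft=stft,
            families=tuple(feat.get("families", ["spectral"])),
            n_spectral=int(feat.get("n_spectral", 3)),
            cv_scheme=cv.pop("scheme", "loso"),
            cv_params=cv,
            classifier=ClassifierSpec(
                clf.get("kind", "svm"), dict(clf.get("params", {}) or {})
            ),
            noise_levels=tuple(noise.get("levels", []) or []),
            seed=int(raw.get("seed", 0)),
        )


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise FormatError("config file must contain a mapping")
    return RunConfig.from_mapping(raw)


def _obtain_cohort(cfg: RunConfig) -> tuple[Cohort, Path | None]:
    if cfg.simulate is not None:
        sim = cfg.simulate
        cohort_cfg = default_config(
            seed=stage_seed(cfg.seed, 0),
            n_improved=int(sim.get("n_improved", 14)),
            n_unimproved=int(sim.get("n_unimproved", 5)),
            n_strides=int(sim.get("n_strides", 200)),
        )
        return generate_cohort(cohort_cfg), None
    return read_cohort(cfg.cohort_csv), Path(cfg.cohort_csv)


def _evaluate(cfg: RunConfig, table: FeatureTable, family: str) -> EvalReport:
    seed = stage_seed(cfg.seed, 2)
    if cfg.cv_scheme == "loso":
        return cv_leave_one_sample_out(
            table, cfg.classifier, seed=seed, feature_family=family
        )
    if cfg.cv_scheme == "lofo":
        return cv_leave_one_fold_out(
            table,
            cfg.classifier,
            n_per_class=int(cfg.cv_params.get("n_per_class", 4)),
            n_repeats=int(cfg.cv_params.get("n_repeats", 50)),
            seed=seed,
            feature_family=family,
        )
    return cv_stratified_kfold(
        table,
        cfg.classifier,
        k=int(cfg.cv_params.get("k", 5)),
        seed=seed,
        feature_family=family,
    )


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Run simulate/load -> extract -> screen -> evaluate [-> noise sweep].

    Writes ``features.csv``, ``screening.csv``, ``report.csv`` and
    ``manifest.json`` into ``cfg.out_dir`` (plus ``cohort.csv`` when the
    cohort was simulated) and returns the artifact paths.  Deterministic
    given the config, including its seed; input files are never mutated.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort, _ = _obtain_cohort(cfg)

    artifacts: dict[str, str] = {}
    if cfg.simulate is not None:
        cohort_path = out_dir / "cohort.csv"
        write_cohort(cohort, cohort_path)
        artifacts["cohort"] = str(cohort_path)

    tables = {
        fam: extract_feature_table(cohort, fam, cfg.stft, cfg.n_spectral)
        for fam in cfg.families
    }
    merged = tables[cfg.families[0]]
    for fam in cfg.families[1:]:
        t = tables[fam]
        names = merged.feature_names + [
            n for n in t.feature_names if n not in merged.feature_names
        ]
        extra = [n for n in t.feature_names if n not in merged.feature_names]
        mat = np.hstack(
            [merged.matrix] + ([t.matrix[:, [t.feature_names.index(n) for n in extra]]] if extra else [])
        )
        merged = FeatureTable(merged.subject_ids, names, mat, merged.labels)
    features_path = out_dir / "features.csv"
    write_feature_table(merged, features_path)
    artifacts["features"] = str(features_path)

    screening = screen_features(merged)
    screening_path = out_dir / "screening.csv"
    screening.to_csv(screening_path, index=False)
    artifacts["screening"] = str(screening_path)

    rows = []
    for fam in cfg.families:
        rows.append(_evaluate(cfg, tables[fam], fam).to_row())
    if cfg.noise_levels:
        extractor = extractor_for(cfg.families[0], cfg.stft, cfg.n_spectral)
        for rep in noise_sweep(
            cohort,
            extractor,
            cfg.classifier,
            levels=cfg.noise_levels,
            seed=stage_seed(cfg.seed, 3),
            feature_family=cfg.families[0],
        ):
            rows.append(rep.to_row())
    report_path = out_dir / "report.csv"
    pd.DataFrame(rows).to_csv(report_path, index=False)
    artifacts["report"] = str(report_path)

    manifest = {
        "config": {
            "out_dir": cfg.out_dir,
            "cohort_csv": cfg.cohort_csv,
            "simulate": cfg.simulate,
            "stft": asdict(cfg.stft),
            "families": list(cfg.families),
            "n_spectral": cfg.n_spectral,
            "cv_scheme": cfg.cv_scheme,
            "cv_params": cfg.cv_params,
            "classifier": {"kind": cfg.classifier.kind, "params": cfg.classifier.params},
            "noise_levels": list(cfg.noise_levels),
            "seed": cfg.seed,
        },
        "versions": {
            "mfc_spectra": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = str(manifest_path)
    return artifacts
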