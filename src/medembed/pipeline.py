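"""End-to-end pipeline: normalize -> count -> merge -> factorize -> benchmark.

A :class:`RunConfig` names the inputs (corpus, dictionary, events,
relationship/type/score tables), the stage parameters, and an output
directory.  :func:`run_pipeline` executes the stages in order, writes
every intermediate artifact in its interchange format, and records all
parameters and derived per-stage seeds in a ``manifest.json`` so a rerun
with the same config is byte-identical.  Any stage failure aborts with
the stage name attached.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from . import io as mio
from .benchmark import relationship_power, human_similarity_correlation
from .cooccur import (
    count_temporal_cooccurrences,
    count_text_cooccurrences,
    merge_counts,
)
from .glove import GloVe, GloVeParams
from .normalize import chunk_windows, normalize_text
from .spectral import RawCountSVD, SPPMIParams, SPPMISVD

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All stage parameters and paths for one pipeline run."""

    out_dir: str
    corpus: str | None = None
    dictionary: str | None = None
    events: str | None = None
    relationships: str | None = None
    semantic_types: str | None = None
    human_scores: str | None = None
    # stage parameters
    window: int = 10
    span_days: int = 30
    temporal_mode: str = "rolling"
    method: str = "svd"          # svd | glove | pca
    alpha: float = 0.75
    k: float = 1.0
    d: int = 500
    sigma_power: float = 0.5
    glove_epochs: int = 25
    glove_lr: float = 0.05
    y_max: float = 100.0
    bench_n: int = 10_000
    bench_level: float = 0.05
    null_mode: str = "matched"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("svd", "glove", "pca"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.corpus is None and self.events is None:
            raise ValueError("config names neither a corpus nor an event stream")
        if self.corpus is not None and self.dictionary is None:
            raise ValueError("a corpus input requires a dictionary")
        SPPMIParams(alpha=self.alpha, k=self.k)  # range validation
        if not 0.0 < self.bench_level < 1.0:
            raise ValueError("benchmark level must be in (0, 1)")
        if self.window < 2 or self.span_days < 1 or self.d < 1:
            raise ValueError("window, span_days and d must be positive (window >= 2)")
        for name in ("corpus", "dictionary", "events", "relationships",
                     "semantic_types", "human_scores"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = mio.read_config(path)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, value in raw.items():
            default = cls.__dataclass_fields__[name].default
            if isinstance(default, bool):
                value = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                value = int(value)
            elif isinstance(default, float):
                value = float(value)
            kwargs[name] = value
        return cls(**kwargs)


def _stage_seed(base: int, stage: str) -> int:
    from zlib import crc32
    return (base * 7919 + crc32(stage.encode())) % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "stage_seeds": {},
        "artifacts": {},
        "results": [],
    }

    def _run(stage, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise PipelineError(stage, exc) from exc

    matrices = []
    if config.corpus is not None:
        def _text():
            dictionary = mio.read_dictionary(config.dictionary)
            with open(config.corpus) as fh:
                docs = [line.rstrip("\n") for line in fh if line.strip()]
            windows = []
            for i, doc in enumerate(docs):
                stream = normalize_text(doc, dictionary, doc_id=str(i))
                if len(stream):
                    windows.extend(chunk_windows(stream, config.window))
            cuis = sorted(set(dictionary.entries.values()))
            from .cooccur import Vocabulary
            vocab = Vocabulary(tuple(cuis))
            return count_text_cooccurrences(windows, vocab)
        matrices.append(_run("normalize+text_counts", _text))
    if config.events is not None:
        def _events():
            events = mio.read_events(config.events)
            from .cooccur import Vocabulary
            vocab = Vocabulary.from_concepts(r.cui for r in events)
            return count_temporal_cooccurrences(
                events, vocab, span_days=config.span_days,
                mode=config.temporal_mode,
            )
        matrices.append(_run("temporal_counts", _events))

    master = _run("merge", lambda: merge_counts(matrices))
    cooc_path = out / "cooccurrence.mtx"
    mio.write_cooccurrence(cooc_path, master)
    manifest["artifacts"]["cooccurrence"] = str(cooc_path)

    svd_seed = _stage_seed(config.seed, "svd")
    manifest["stage_seeds"]["svd"] = svd_seed

    def _factorize():
        d = min(config.d, len(master.vocab))
        if config.method == "svd":
            params = SPPMIParams(alpha=config.alpha, k=config.k)
            model = SPPMISVD(master, params)
            sppmi_path = out / "sppmi.mtx"
            mio.write_sppmi_values(sppmi_path, model.sppmi.values, master.vocab)
            manifest["artifacts"]["sppmi"] = str(sppmi_path)
            return model.fit(
                d=d, sigma_power=config.sigma_power, seed=svd_seed
            ).embedding
        if config.method == "pca":
            return RawCountSVD(master).fit(d=d, seed=svd_seed).embedding
        params = GloVeParams(
            d=d, y_max=config.y_max, epochs=config.glove_epochs,
            learning_rate=config.glove_lr,
            seed=_stage_seed(config.seed, "glove"),
        )
        manifest["stage_seeds"]["glove"] = params.seed
        return GloVe(master, params).fit().embedding

    embedding = _run("factorize", _factorize)
    emb_path = out / "embeddings.w2v.txt"
    mio.write_embeddings(emb_path, embedding, fmt="word2vec")
    manifest["artifacts"]["embeddings"] = str(emb_path)

    results = []
    if config.relationships is not None and config.semantic_types is not None:
        def _power():
            rels = mio.read_relationships(config.relationships)
            types = mio.read_semantic_types(config.semantic_types)
            return relationship_power(
                embedding, rels, types, n=config.bench_n,
                level=config.bench_level,
                seed=_stage_seed(config.seed, "bench"),
                null_mode=config.null_mode,
            )
        results.append(_run("benchmark_power", _power))
        manifest["stage_seeds"]["bench"] = _stage_seed(config.seed, "bench")
    if config.human_scores is not None:
        def _human():
            human = mio.read_human_scores(config.human_scores)
            return human_similarity_correlation(embedding, human)
        results.append(_run("benchmark_human", _human))

    if results:
        results_path = out / "results.tsv"
        mio.write_results(results_path, results)
        manifest["artifacts"]["results"] = str(results_path)
        manifest["results"] = [
            {
                "benchmark": r.name, "metric": r.metric, "value": r.value,
                "n_evaluable": r.n_evaluable, "n_total": r.n_total,
            }
            for r in results
        ]

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
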