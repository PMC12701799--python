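"""End-to-end benchmark orchestration.

Per dataset: obtain an alignment (simulate along the reference tree, load
an empirical file, or simulate gapless and superimpose an empirical gap
mask), run every configured inferrer, evaluate all trees under identical
settings for comparable log-likelihoods, compare topologies to the
reference, run the AU plausibility test over the whole candidate set
(reference included), estimate dataset difficulty from replicate searches,
and emit one record per tool.  Results aggregate into difficulty-bucketed
tables.  Completed work is detected on disk, so re-runs and added tools
only compute what is missing.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from .autest import DEFAULT_SCALES, plausible_set
from .corpus import CorpusEntry, percentile_filter, read_corpus, select_representatives
from .difficulty import difficulty_bucket, difficulty_from_searches
from .inference import (
    BUILTIN_TOOLS,
    ToolResult,
    bionj,
    jc_distance_matrix,
    nni_ml_search,
    parsimony_tree,
    run_external_tool,
)
from .likelihood import SiteLnLMatrix, evaluate_tree, site_log_likelihoods
from .models import GTRGammaModel, IndelModel
from .msa import MSA, gap_mask, read_fasta, superimpose_gaps, write_fasta
from .simulate import simulate_gapless, simulate_with_indels
from .trees import (
    Tree,
    ntd_distance,
    parse_newick,
    quartet_distance,
    rf_distance,
    write_newick,
)

__all__ = [
    "RunConfig",
    "BenchmarkRecord",
    "RunResult",
    "best_known_reference",
    "run_dataset",
    "aggregate",
    "run_pipeline",
]

log = logging.getLogger(__name__)

MODES = ("simulated-truth", "empirical-bestknown", "gap-superimposed")
REFERENCE_ID = "reference"


@dataclass
class RunConfig:
    """Benchmark run settings (mirrors the YAML config file)."""

    out_dir: str
    corpus_path: str | None = None
    entries: list[CorpusEntry] | None = None
    mode: str = "simulated-truth"
    tools: tuple[str, ...] = BUILTIN_TOOLS
    seed: int = 0
    percentile: float | None = None
    n_buckets: int | None = None
    au_alpha: float = 0.05
    au_B: int = 1000
    au_scales: tuple[float, ...] = DEFAULT_SCALES
    difficulty_searches: int = 20
    difficulty_au_B: int = 500
    thorough_searches: int = 10
    indel: IndelModel | None = None
    external_tools: dict = field(default_factory=dict)
    opt_flags: frozenset[str] = frozenset({"brlens"})
    quartet_max_taxa: int = 40
    include_reference_in_au: bool = True

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.corpus_path is None and self.entries is None:
            raise ValueError("config needs a corpus_path or in-memory entries")
        if not self.tools:
            raise ValueError("no tools configured")
        for t in self.tools:
            if t not in BUILTIN_TOOLS and t not in self.external_tools:
                raise ValueError(
                    f"tool {t!r} is neither built-in {BUILTIN_TOOLS} nor registered "
                    f"in external_tools {sorted(self.external_tools)}"
                )
        if not 0 < self.au_alpha < 1:
            raise ValueError("au_alpha must be in (0, 1)")
        if self.difficulty_searches < 1:
            raise ValueError("difficulty_searches must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "indel" in raw and raw["indel"] is not None:
            raw["indel"] = IndelModel(**raw["indel"])
        if "tools" in raw:
            raw["tools"] = tuple(raw["tools"])
        if "opt_flags" in raw:
            raw["opt_flags"] = frozenset(raw["opt_flags"])
        if "au_scales" in raw:
            raw["au_scales"] = tuple(raw["au_scales"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class BenchmarkRecord:
    """One inferrer on one dataset."""

    dataset: str
    tool: str
    status: str  # ok | skipped | failed
    rf_raw: float = np.nan
    rf_normalized: float = np.nan
    ntd: float = np.nan
    quartet: float = np.nan
    lnl: float = np.nan
    delta_lnl: float = np.nan
    rel_delta_lnl: float = np.nan
    au_p: float = np.nan
    plausible: bool = False
    difficulty: float = np.nan
    bucket: int = -1
    provenance: str = ""
    message: str = ""


@dataclass
class RunResult:
    out_dir: Path
    records: pd.DataFrame
    aggregate: pd.DataFrame
    spearman: dict[str, float]
    n_inferences_computed: int
    n_inferences_cached: int
    n_datasets_skipped: int


def _stage_seed(seed: int, dataset_id: str, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [int(seed), zlib.crc32(dataset_id.encode()), zlib.crc32(stage.encode())]
    )


def best_known_reference(
    candidates: dict[str, Tree],
    thorough: list[Tree],
    msa: MSA,
    model: GTRGammaModel,
    opt_flags: frozenset[str] = frozenset({"brlens"}),
) -> tuple[Tree, str]:
    """Highest-lnL tree among the thorough searches and the tool trees.

    All trees are evaluated under identical optimization flags.  Exact lnL
    ties resolve by precedence: thorough searches first, then tools in
    registration order.  Returns (tree, provenance label).
    """
    if not candidates and not thorough:
        raise ValueError("no candidate trees")
    best: tuple[float, str, Tree] | None = None
    ordered = [(f"thorough-{i}", t) for i, t in enumerate(thorough)]
    ordered += list(candidates.items())
    for name, tree in ordered:
        lnl, opt_tree, _ = evaluate_tree(tree, msa, model, optimize=opt_flags)
        if best is None or lnl > best[0]:
            best = (lnl, name, opt_tree)
    return best[2], best[1]


def _infer_one(
    tool: str,
    msa: MSA,
    model: GTRGammaModel,
    seed_ss: np.random.SeedSequence,
    cfg: RunConfig,
    msa_path: Path | None,
    workdir: Path | None,
) -> ToolResult:
    try:
        if tool == "bionj":
            return ToolResult(tool, "ok", tree=bionj(jc_distance_matrix(msa)))
        if tool == "parsimony":
            return ToolResult(
                tool, "ok", tree=parsimony_tree(msa, seed=seed_ss)
            )
        if tool == "nni-ml":
            start = bionj(jc_distance_matrix(msa))
            tree, _ = nni_ml_search(msa, model, start)
            return ToolResult(tool, "ok", tree=tree)
        if msa_path is None:
            raise ValueError("external tools need an alignment file on disk")
        return run_external_tool(
            tool, msa_path, {"tools": cfg.external_tools}, workdir=workdir
        )
    except Exception as exc:  # a failing tool must not abort the dataset
        log.exception("tool %s failed", tool)
        return ToolResult(tool, "failed", message=str(exc))


def _dataset_difficulty(
    msa: MSA, model: GTRGammaModel, cfg: RunConfig, ss: np.random.SeedSequence
) -> tuple[float, int]:
    """Ground-truth difficulty from replicate parsimony searches + AU test."""
    n = cfg.difficulty_searches
    seeds = ss.spawn(n + 1)
    trees = [parsimony_tree(msa, seed=s) for s in seeds[:n]]
    if n == 1:
        flags = [True]
    else:
        rows = []
        for t in trees:
            lnl, opt_t, opt_m = evaluate_tree(t, msa, model, optimize=cfg.opt_flags)
            rows.append(site_log_likelihoods(opt_t, msa, opt_m))
        m = SiteLnLMatrix([f"s{i}" for i in range(n)], np.vstack(rows))
        results = plausible_set(
            m, alpha=cfg.au_alpha, scales=cfg.au_scales,
            B=cfg.difficulty_au_B, seed=seeds[n],
        )
        flags = [r.plausible for r in results]
    _, d = difficulty_from_searches(trees, flags)
    return d, difficulty_bucket(d)


def _obtain_msa_and_reference(
    entry: CorpusEntry, cfg: RunConfig, workdir: Path | None
) -> tuple[MSA, Tree | None, Path | None]:
    """Returns (msa, reference tree or None for best-known mode, msa path)."""
    msa_path = workdir / "msa.fasta" if workdir else None
    if cfg.mode == "empirical-bestknown":
        if entry.msa_path is None:
            raise ValueError(f"{entry.id}: empirical mode needs msa_path")
        return read_fasta(entry.msa_path), None, Path(entry.msa_path)

    tree = entry.load_tree()
    sim_seed = _stage_seed(cfg.seed, entry.id, "simulate")
    if msa_path is not None and msa_path.exists():
        msa = read_fasta(msa_path)
    elif cfg.mode == "simulated-truth":
        if cfg.indel is not None:
            msa = simulate_with_indels(tree, entry.model, entry.n_sites, cfg.indel, sim_seed)
        else:
            msa = simulate_gapless(tree, entry.model, entry.n_sites, sim_seed)
    else:  # gap-superimposed
        msa = simulate_gapless(tree, entry.model, entry.n_sites, sim_seed)
        if entry.msa_path is not None:
            mask = gap_mask(read_fasta(entry.msa_path).row_order(msa.taxa))
        elif cfg.indel is not None:
            gappy = simulate_with_indels(
                tree, entry.model, entry.n_sites, cfg.indel,
                _stage_seed(cfg.seed, entry.id, "gapmask"),
            )
            mask = gap_mask(gappy)[:, : msa.n_sites]
            if mask.shape[1] < msa.n_sites:
                pad = np.zeros((msa.n_taxa, msa.n_sites - mask.shape[1]), bool)
                mask = np.hstack([mask, pad])
        else:
            raise ValueError(
                f"{entry.id}: gap-superimposed mode needs msa_path or an indel model"
            )
        msa = superimpose_gaps(msa, mask)
    if msa_path is not None and not msa_path.exists():
        write_fasta(msa, msa_path)
    return msa, tree, msa_path


def run_dataset(
    entry: CorpusEntry, cfg: RunConfig, workdir: str | Path | None = None
) -> tuple[list[BenchmarkRecord], dict]:
    """Run every configured tool on one dataset; never raises per-tool.

    With a `workdir`, finished artifacts (alignment, per-tool trees) are
    reused; the counters in the returned dict say what was recomputed.
    """
    cfg.validate()
    workdir = Path(workdir) if workdir is not None else None
    if workdir is not None:
        (workdir / "trees").mkdir(parents=True, exist_ok=True)
    counters = {"inferences_computed": 0, "inferences_cached": 0}

    msa, reference, msa_path = _obtain_msa_and_reference(entry, cfg, workdir)

    # tree inference (cached per tool)
    results: dict[str, ToolResult] = {}
    tool_ss = _stage_seed(cfg.seed, entry.id, "tools").spawn(len(cfg.tools))
    for tool, ss in zip(cfg.tools, tool_ss):
        cache = workdir / "trees" / f"{tool}.nwk" if workdir else None
        if cache is not None and cache.exists():
            results[tool] = ToolResult(tool, "ok", tree=parse_newick(cache.read_text()))
            counters["inferences_cached"] += 1
            continue
        res = _infer_one(tool, msa, entry.model, ss, cfg, msa_path, workdir)
        results[tool] = res
        if res.status == "ok":
            counters["inferences_computed"] += 1
            if cache is not None:
                cache.write_text(write_newick(res.tree) + "\n")

    # reference tree
    if cfg.mode == "empirical-bestknown":
        thorough_ss = _stage_seed(cfg.seed, entry.id, "thorough").spawn(
            cfg.thorough_searches
        )
        thorough = [parsimony_tree(msa, seed=s) for s in thorough_ss]
        candidates = {t: r.tree for t, r in results.items() if r.status == "ok"}
        reference, provenance = best_known_reference(
            candidates, thorough, msa, entry.model, cfg.opt_flags
        )
    else:
        provenance = "true-tree"
    if workdir is not None:
        (workdir / "reference.nwk").write_text(write_newick(reference) + "\n")

    # comparable likelihood evaluation + per-site vectors
    ids: list[str] = [REFERENCE_ID]
    rows: list[np.ndarray] = []
    lnls: dict[str, float] = {}
    ref_lnl, ref_opt, ref_model = evaluate_tree(
        reference, msa, entry.model, optimize=cfg.opt_flags
    )
    lnls[REFERENCE_ID] = ref_lnl
    rows.append(site_log_likelihoods(ref_opt, msa, ref_model))
    for tool, res in results.items():
        if res.status != "ok":
            continue
        lnl, opt_t, opt_m = evaluate_tree(
            res.tree, msa, entry.model, optimize=cfg.opt_flags
        )
        lnls[tool] = lnl
        ids.append(tool)
        rows.append(site_log_likelihoods(opt_t, msa, opt_m))
    site_matrix = SiteLnLMatrix(ids, np.vstack(rows))
    if workdir is not None:
        site_matrix.to_tsv(workdir / "sitelnl.tsv")

    # AU plausibility over the full candidate set (reference included)
    au: dict[str, tuple[float, bool]] = {}
    if site_matrix.n_trees >= 2:
        au_seed = _stage_seed(cfg.seed, entry.id, "au")
        for r in plausible_set(
            site_matrix, alpha=cfg.au_alpha, scales=cfg.au_scales,
            B=cfg.au_B, seed=au_seed,
        ):
            au[r.tree_id] = (r.p_au, r.plausible)
    else:
        au[REFERENCE_ID] = (1.0, True)
    if workdir is not None:
        with open(workdir / "au.tsv", "w") as fh:
            fh.write("tree\tp_au\tplausible\n")
            for tid, (p, fl) in au.items():
                fh.write(f"{tid}\t{p:.6g}\t{int(fl)}\n")

    # dataset difficulty (cached)
    diff_cache = workdir / "difficulty.json" if workdir else None
    if diff_cache is not None and diff_cache.exists():
        dd = json.loads(diff_cache.read_text())
        diff, bucket = dd["difficulty"], dd["bucket"]
    else:
        diff, bucket = _dataset_difficulty(
            msa, entry.model, cfg, _stage_seed(cfg.seed, entry.id, "difficulty")
        )
        if diff_cache is not None:
            diff_cache.write_text(json.dumps({"difficulty": diff, "bucket": bucket}))

    # records
    n = msa.n_taxa
    records: list[BenchmarkRecord] = []

    def distances(tree: Tree) -> tuple[float, float, float, float]:
        raw, norm = rf_distance(reference, tree)
        ntd = ntd_distance(reference, tree)
        if n <= cfg.quartet_max_taxa:
            qd = quartet_distance(reference, tree, max_leaves=cfg.quartet_max_taxa)
        else:
            qd = np.nan
        return float(raw), float(norm), float(ntd), float(qd)

    p_ref, pl_ref = au.get(REFERENCE_ID, (np.nan, True))
    records.append(
        BenchmarkRecord(
            dataset=entry.id, tool=REFERENCE_ID, status="ok",
            rf_raw=0.0, rf_normalized=0.0, ntd=0.0,
            quartet=0.0 if n <= cfg.quartet_max_taxa else np.nan,
            lnl=ref_lnl, delta_lnl=0.0, rel_delta_lnl=0.0,
            au_p=p_ref, plausible=pl_ref,
            difficulty=diff, bucket=bucket, provenance=provenance,
        )
    )
    for tool, res in results.items():
        if res.status != "ok":
            records.append(
                BenchmarkRecord(
                    dataset=entry.id, tool=tool, status=res.status,
                    difficulty=diff, bucket=bucket, message=res.message,
                )
            )
            continue
        raw, norm, ntd, qd = distances(res.tree)
        p, fl = au.get(tool, (np.nan, False))
        delta = ref_lnl - lnls[tool]
        records.append(
            BenchmarkRecord(
                dataset=entry.id, tool=tool, status="ok",
                rf_raw=raw, rf_normalized=norm, ntd=ntd, quartet=qd,
                lnl=lnls[tool], delta_lnl=delta,
                rel_delta_lnl=delta / abs(ref_lnl) if ref_lnl != 0 else np.nan,
                au_p=p, plausible=fl,
                difficulty=diff, bucket=bucket, provenance=provenance,
            )
        )
    return records, counters


def aggregate(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-(bucket, tool) summary table plus per-tool difficulty-RF Spearman.

    The table carries counts, means and medians of every distance and the
    lnL differences, and the fraction of plausible trees.  The Spearman
    coefficients correlate dataset difficulty with normalized RF distance
    across datasets, one value per tool.
    """
    ok = records[records["status"] == "ok"]
    if ok.empty:
        raise ValueError("no successful records to aggregate")
    metrics = ["rf_normalized", "ntd", "quartet", "delta_lnl", "rel_delta_lnl"]
    rows = []
    for (bucket, tool), grp in ok.groupby(["bucket", "tool"]):
        row: dict = {"bucket": bucket, "tool": tool, "count": len(grp)}
        for mcol in metrics:
            row[f"{mcol}_mean"] = grp[mcol].mean()
            row[f"{mcol}_median"] = grp[mcol].median()
        row["plausible_fraction"] = grp["plausible"].mean()
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(["bucket", "tool"]).reset_index(drop=True)
    spearman: dict[str, float] = {}
    for tool, grp in ok.groupby("tool"):
        if tool == REFERENCE_ID or len(grp) < 3:
            continue
        rho = spearmanr(grp["difficulty"], grp["rf_normalized"]).statistic
        spearman[str(tool)] = float(rho) if np.isfinite(rho) else 0.0
    return table, spearman


def _load_entries(cfg: RunConfig) -> list[CorpusEntry]:
    entries = cfg.entries if cfg.entries is not None else read_corpus(cfg.corpus_path)
    if cfg.percentile is not None:
        entries = percentile_filter(entries, q=cfg.percentile)
    if cfg.n_buckets is not None:
        entries = select_representatives(
            entries, cfg.n_buckets, seed=_stage_seed(cfg.seed, "corpus", "select")
        )
    return entries


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Run the whole benchmark; idempotent and resumable.

    A dataset whose artifacts and records already cover the configured
    tools is not recomputed; a newly added tool triggers only its own
    inference (plus the comparison stage, which depends on the candidate
    set).  Writes records.tsv, aggregate.tsv, summary.json and run.log in
    the output directory.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    (out / "datasets").mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setLevel(logging.INFO)
    log.addHandler(fh)
    try:
        log.info("run config: mode=%s tools=%s seed=%d alpha=%g B=%d searches=%d",
                 cfg.mode, cfg.tools, cfg.seed, cfg.au_alpha, cfg.au_B,
                 cfg.difficulty_searches)
        entries = _load_entries(cfg)
        all_records: list[pd.DataFrame] = []
        n_comp = n_cached = n_skipped = 0
        for entry in entries:
            wd = out / "datasets" / entry.id
            stamp = wd / "done.json"
            rec_path = wd / "records.tsv"
            if stamp.exists() and rec_path.exists():
                meta = json.loads(stamp.read_text())
                if set(cfg.tools) <= set(meta.get("tools", [])):
                    all_records.append(pd.read_csv(rec_path, sep="\t"))
                    n_skipped += 1
                    log.info("%s: up to date, skipped", entry.id)
                    continue
            recs, counters = run_dataset(entry, cfg, workdir=wd)
            n_comp += counters["inferences_computed"]
            n_cached += counters["inferences_cached"]
            df = pd.DataFrame([asdict(r) for r in recs])
            df.to_csv(rec_path, sep="\t", index=False)
            stamp.write_text(json.dumps({"tools": sorted(cfg.tools), "seed": cfg.seed,
                                         "mode": cfg.mode}))
            all_records.append(df)
            log.info("%s: %d inferences computed, %d cached", entry.id,
                     counters["inferences_computed"], counters["inferences_cached"])
        records = pd.concat(all_records, ignore_index=True)
        records.to_csv(out / "records.tsv", sep="\t", index=False)
        table, spearman = aggregate(records)
        table.to_csv(out / "aggregate.tsv", sep="\t", index=False)
        summary = {
            "n_datasets": len(entries),
            "tools": list(cfg.tools),
            "mode": cfg.mode,
            "seed": cfg.seed,
            "au_alpha": cfg.au_alpha,
            "spearman_difficulty_rf": spearman,
            "inferences_computed": n_comp,
            "inferences_cached": n_cached,
            "datasets_skipped": n_skipped,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        return RunResult(out, records, table, spearman, n_comp, n_cached, n_skipped)
    finally:
        log.removeHandler(fh)
        fh.close()
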