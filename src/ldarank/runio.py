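"""Readers and writers for run files, passage fixtures, gold files and
model dumps.

Two run-file dialects are supported and auto-detected by column count:

* classic 6-column TREC: query_id Q0 doc_id rank score tag
* 7-column genomics passage dialect: query_id doc_id passage_start
  passage_length rank score tag

The writer emits whichever dialect was read, with the same field order.
Passage fixtures are UTF-8 TSV (query_id, passage_id, rank, score,
text; text last, may contain spaces); gold files are TSV (query_id,
passage_id, semicolon-joined aspect labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .evaluation import GoldAspects
from .lda import LdaConfig, TopicModel
from .rerank import Ranking


class RunFileError(ValueError):
    pass


@dataclass
class RunEntry:
    query_id: str
    passage_id: str
    rank: int
    score: float
    tag: str
    extra: tuple[str, ...] = ()   # (passage_start, passage_length) in the 7-column dialect


@dataclass
class Run:
    """A ranked run: per-query entries sorted by rank, plus its dialect."""

    entries: dict[str, list[RunEntry]]
    dialect: int  # 6 or 7
    tag: str

    def rankings(self) -> dict[str, Ranking]:
        return {
            qid: Ranking(qid, [e.passage_id for e in ents])
            for qid, ents in self.entries.items()
        }


def read_run(path: str | Path) -> Run:
    """Parse a run file; dialect is detected from the column count."""
    entries: dict[str, list[RunEntry]] = {}
    dialect = None
    tag = "run"
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) not in (6, 7):
                raise RunFileError(f"{path}:{lineno}: expected 6 or 7 columns, got {len(fields)}")
            if dialect is None:
                dialect = len(fields)
            elif dialect != len(fields):
                raise RunFileError(f"{path}:{lineno}: mixed dialects ({dialect} vs {len(fields)} columns)")
            try:
                if dialect == 6:
                    qid, _q0, pid, rank, score, tag = fields
                    extra: tuple[str, ...] = ()
                else:
                    qid, pid, start, length, rank, score, tag = fields
                    extra = (start, length)
                entry = RunEntry(qid, pid, int(rank), float(score), tag, extra)
            except ValueError as exc:
                raise RunFileError(f"{path}:{lineno}: {exc}") from exc
            entries.setdefault(qid, []).append(entry)
    if dialect is None:
        raise RunFileError(f"{path}: empty run file")
    for qid, ents in entries.items():
        ents.sort(key=lambda e: e.rank)
    return Run(entries, dialect, tag)


def write_run(run: Run, rankings: dict[str, Ranking], path: str | Path, tag: str | None = None) -> None:
    """Write re-ranked rankings in the run's own dialect.

    The rank column is the new position and scores are strictly
    decreasing; passage-offset fields are carried over per passage.
    """
    tag = tag or run.tag
    with open(path, "w", encoding="utf-8") as fh:
        for qid in run.entries:
            by_pid = {e.passage_id: e for e in run.entries[qid]}
            order = rankings[qid].order if qid in rankings else [e.passage_id for e in run.entries[qid]]
            n = len(order)
            for pos, pid in enumerate(order, start=1):
                e = by_pid[pid]
                score = float(n - pos + 1)
                if run.dialect == 6:
                    fh.write(f"{qid} Q0 {pid} {pos} {score:g} {tag}\n")
                else:
                    start, length = e.extra
                    fh.write(f"{qid} {pid} {start} {length} {pos} {score:g} {tag}\n")


def read_passages(path: str | Path) -> dict[str, list[tuple[str, str, int, float, str]]]:
    """Read a passage fixture file into per-query raw-record lists."""
    out: dict[str, list[tuple[str, str, int, float, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.rstrip("\n"):
                continue
            parts = line.rstrip("\n").split("\t", 4)
            if len(parts) != 5:
                raise RunFileError(f"{path}:{lineno}: expected 5 tab-separated columns")
            qid, pid, rank, score, text = parts
            out.setdefault(qid, []).append((qid, pid, int(rank), float(score), text))
    for recs in out.values():
        recs.sort(key=lambda r: r[2])
    return out


def write_passages(records: dict[str, list[tuple[str, str, int, float, str]]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for qid in records:
            for _, pid, rank, score, text in records[qid]:
                fh.write(f"{qid}\t{pid}\t{rank}\t{score:g}\t{text}\n")


def read_gold(path: str | Path) -> dict[str, GoldAspects]:
    """Read gold aspect annotations (TSV: query, passage, labels)."""
    relevant: dict[str, dict[str, set[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise RunFileError(f"{path}:{lineno}: expected 3 tab-separated columns")
            qid, pid, labels = parts
            relevant.setdefault(qid, {})[pid] = {l for l in labels.split(";") if l}
    return {
        qid: GoldAspects(qid, rel, set().union(*rel.values()) if rel else set())
        for qid, rel in relevant.items()
    }


def write_gold(gold: dict[str, GoldAspects], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for qid in gold:
            for pid, labels in gold[qid].relevant.items():
                fh.write(f"{qid}\t{pid}\t{';'.join(sorted(labels))}\n")


def _write_matrix(path: Path, m: np.ndarray, header: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {header}\n")
        for row in m:
            fh.write("\t".join(f"{x:.12g}" for x in row) + "\n")


def _read_matrix(path: Path) -> np.ndarray:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            rows.append([float(x) for x in line.split("\t")])
    return np.array(rows)


def dump_model(model: TopicModel, outdir: str | Path, curve: list[tuple[int, float]] | None = None) -> None:
    """Write θ, φ, the echoed config and the evidence curve to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    D, T = model.theta.shape
    V = model.phi.shape[1]
    _write_matrix(outdir / "theta.tsv", model.theta, f"theta D={D} T={T}")
    _write_matrix(outdir / "phi.tsv", model.phi, f"phi T={T} V={V}")
    cfg = {
        "T": model.config.T,
        "beta": model.config.beta,
        "alpha": model.config.alpha,
        "alpha_T_constant": model.config.alpha_T_constant,
        "n_sweeps": model.config.n_sweeps,
        "burn_in": model.config.burn_in,
        "sample_lag": model.config.sample_lag,
        "seed": model.config.seed,
        "log_evidence": model.log_evidence,
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg), encoding="utf-8")
    if curve is not None:
        with open(outdir / "evidence.tsv", "w", encoding="utf-8") as fh:
            fh.write("T\tlog_evidence\n")
            for T_val, ev in curve:
                fh.write(f"{T_val}\t{ev:.6f}\n")


def dump_importance(mu: np.ndarray, sigma: np.ndarray, Theta: np.ndarray, outdir: str | Path) -> None:
    """Write Θ (same matrix dialect as θ) and the per-aspect moments."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    D, T = Theta.shape
    _write_matrix(outdir / "Theta.tsv", Theta, f"Theta D={D} T={T}")
    with open(outdir / "moments.tsv", "w", encoding="utf-8") as fh:
        fh.write("t\tmu\tsigma\n")
        for t in range(T):
            fh.write(f"{t}\t{mu[t]:.12g}\t{sigma[t]:.12g}\n")


def load_model(outdir: str | Path) -> TopicModel:
    outdir = Path(outdir)
    cfg = yaml.safe_load((outdir / "config.yaml").read_text(encoding="utf-8"))
    config = LdaConfig(
        T=cfg["T"], beta=cfg["beta"], alpha_T_constant=cfg["alpha_T_constant"],
        n_sweeps=cfg["n_sweeps"], burn_in=cfg["burn_in"],
        sample_lag=cfg["sample_lag"], seed=cfg["seed"],
    )
    return TopicModel(
        theta=_read_matrix(outdir / "theta.tsv"),
        phi=_read_matrix(outdir / "phi.tsv"),
        config=config,
        log_evidence=float(cfg["log_evidence"]),
    )
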