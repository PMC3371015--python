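"""File formats and dataset assembly.

TSV dialects:

* labels:        ``accession<TAB>Location1;Location2``
* GO map:        ``accession<TAB>GO:...;GO:...`` or the 3-column
                 variant ``accession<TAB>namespace<TAB>terms``
* feature view:  TSV with a header row and an accession index column
* predictions:   accession, one probability column per label, the
                 decided set (semicolon-joined) and the full ranking

The model archive is a single compressed ``.npz`` bundling a JSON
metadata document with the numeric blobs (C, a, w, the Laplace mode
and factors, training features, bandwidths), so a saved model predicts
without refitting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .data import FeatureView, MultiViewDataset, sanitize_sequence
from .metrics import EvaluationReport
from .model import MultiLabelGP, PosteriorApprox

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, drop_invalid: bool = False) -> list[tuple[str, str]]:
    """(accession, sanitized sequence) pairs; the accession is the first
    whitespace-delimited token of the header."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id.split()[0]
        try:
            out.append((acc, sanitize_sequence(str(rec.seq), accession=acc)))
        except ValueError:
            if not drop_invalid:
                raise
            logger.warning("dropping record %s: invalid residues", acc)
    return out


def read_labels_tsv(path: str | Path) -> dict[str, list[str]]:
    """accession -> list of location names (semicolon-separated field)."""
    out: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        acc, _, labels = line.partition("\t")
        acc = acc.strip()
        if acc in out:
            raise ValueError(f"duplicate accession {acc!r} in labels file")
        out[acc] = [s.strip() for s in labels.split(";") if s.strip()]
    return out


def read_go_map(path: str | Path, namespace: str | None = None) -> dict[str, set[str]]:
    """accession -> GO term set; the optional middle column restricts to
    one namespace (process / function / component)."""
    out: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) == 3:
            acc, ns, terms = parts
            if namespace not in (None, "all") and ns.strip() != namespace:
                continue
        elif len(parts) == 2:
            acc, terms = parts
        else:
            raise ValueError(f"GO map line has {len(parts)} columns: {line!r}")
        out.setdefault(acc.strip(), set()).update(
            t.strip() for t in terms.split(";") if t.strip()
        )
    return out


def read_feature_tsv(path: str | Path, name: str | None = None):
    """Feature view from TSV (accession index + header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    view = FeatureView(
        name=name or Path(path).stem,
        matrix=df.to_numpy(dtype=float),
        column_names=[str(c) for c in df.columns],
    )
    return [str(i) for i in df.index], view


def write_feature_tsv(path: str | Path, accessions: list[str], view: FeatureView) -> None:
    cols = view.column_names or [f"f{j}" for j in range(view.n_features)]
    pd.DataFrame(view.matrix, index=accessions, columns=cols).to_csv(
        path, sep="\t", index_label="accession", float_format="%.12g"
    )


def write_labels_tsv(path: str | Path, accessions: list[str],
                     Y: np.ndarray, label_names: list[str]) -> None:
    with open(path, "w") as fh:
        for acc, row in zip(accessions, np.asarray(Y)):
            labs = [label_names[k] for k in np.flatnonzero(row > 0)]
            fh.write(f"{acc}\t{';'.join(labs)}\n")


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def align_views(
    per_source_accessions: list[list[str]],
    views: list[FeatureView],
    labels: dict[str, list[str]] | None = None,
    label_order: list[str] | None = None,
) -> MultiViewDataset:
    """Row-align feature views (and labels) on the accession
    intersection, dropping samples missing from any source.

    Label names freeze in first-seen order unless ``label_order`` is
    given (prediction against a trained model).
    """
    common = None
    for accs in per_source_accessions:
        if len(set(accs)) != len(accs):
            dupes = sorted({a for a in accs if accs.count(a) > 1})
            raise ValueError(f"duplicate accessions: {dupes[:5]}")
        s = set(accs)
        common = s if common is None else common & s
    if labels is not None:
        common = common & set(labels)
    if not common:
        raise ValueError("zero overlapping accessions across input sources")
    order = [a for a in per_source_accessions[0] if a in common]
    dropped = len(per_source_accessions[0]) - len(order)
    if dropped:
        logger.warning("%d sample(s) dropped (missing from some source)", dropped)

    aligned = []
    for accs, view in zip(per_source_accessions, views):
        idx = {a: i for i, a in enumerate(accs)}
        rows = np.array([idx[a] for a in order])
        aligned.append(FeatureView(view.name, view.matrix[rows], view.column_names))

    Y = None
    names = None
    if labels is not None:
        if label_order is None:
            names = []
            for a in order:
                for lab in labels[a]:
                    if lab not in names:
                        names.append(lab)
        else:
            names = list(label_order)
        name_idx = {lab: k for k, lab in enumerate(names)}
        Y = -np.ones((len(order), len(names)), dtype=int)
        for i, a in enumerate(order):
            for lab in labels[a]:
                if lab in name_idx:
                    Y[i, name_idx[lab]] = 1
                else:
                    logger.warning("accession %s: unknown label %r ignored", a, lab)
    return MultiViewDataset(accessions=order, views=aligned, Y=Y, label_names=names)


# ---------------------------------------------------------------------------
# model archive
# ---------------------------------------------------------------------------


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_model(
    model: MultiLabelGP,
    path: str | Path,
    label_names: list[str],
    extra_meta: dict | None = None,
) -> None:
    """Bundle metadata + numeric blobs into one compressed archive."""
    meta = {
        "format": "mmlgp-model-v1",
        "label_names": label_names,
        "view_names": model.view_names_,
        "threshold": model.threshold,
        "mc_samples": model.mc_samples,
        "proba_method": model.proba_method,
        "learn_C": model.learn_C,
        "learn_a": model.learn_a,
        "use_weights": model.use_weights,
        "seed": model.seed,
    }
    meta.update(extra_meta or {})
    meta["config_hash"] = config_hash(meta)
    arrays = {
        "C": model.C_, "a": model.a_, "theta": model.theta_, "w": model.w_,
        "active_labels": model.active_labels_,
        "n_labels_total": np.array([model.n_labels_total_]),
        "G_hat": model.posterior_.G_hat, "alpha": model.posterior_.alpha,
        "W": model.posterior_.W, "L": model.posterior_.L,
        "dloglik": model.posterior_.dloglik,
        "log_marginal": np.array([model.posterior_.log_marginal]),
        "K": model.posterior_.K,
        "Y": model.Y_,
    }
    for j, X in enumerate(model.train_views_):
        arrays[f"train_view_{j}"] = X
    np.savez_compressed(path, meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> tuple[MultiLabelGP, dict]:
    """Rebuild a fitted model (no refitting) and its metadata."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta.get("format") != "mmlgp-model-v1":
            raise ValueError(f"{path}: not a model archive")
        model = MultiLabelGP(
            learn_C=meta["learn_C"], learn_a=meta["learn_a"],
            use_weights=meta["use_weights"], threshold=meta["threshold"],
            mc_samples=meta["mc_samples"], proba_method=meta["proba_method"],
            seed=meta["seed"],
        )
        model.view_names_ = meta["view_names"]
        model.C_, model.a_ = z["C"], z["a"]
        model.theta_, model.w_ = z["theta"], z["w"]
        model.active_labels_ = z["active_labels"]
        model.n_labels_total_ = int(z["n_labels_total"][0])
        model.Y_ = z["Y"]
        model.train_views_ = [
            z[f"train_view_{j}"] for j in range(len(meta["view_names"]))
        ]
        model.posterior_ = PosteriorApprox(
            G_hat=z["G_hat"], alpha=z["alpha"], W=z["W"], L=z["L"],
            dloglik=z["dloglik"], log_marginal=float(z["log_marginal"][0]),
            grad_norm=0.0, C=z["C"], K=z["K"], n_iter=0,
        )
    return model, meta


# ---------------------------------------------------------------------------
# prediction / report output
# ---------------------------------------------------------------------------


def write_predictions_tsv(
    path: str | Path,
    accessions: list[str],
    results,
    label_names: list[str],
    header_meta: dict | None = None,
) -> None:
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        cols = ["accession"] + [f"p:{lab}" for lab in label_names] + ["decided", "ranking"]
        fh.write("\t".join(cols) + "\n")
        for acc, r in zip(accessions, results):
            probs = "\t".join(f"{p:.6f}" for p in r.probabilities)
            decided = ";".join(label_names[k] for k in np.flatnonzero(r.decided))
            ranking = ";".join(label_names[k] for k in r.ranking)
            fh.write(f"{acc}\t{probs}\t{decided}\t{ranking}\n")


def read_predictions_tsv(path: str | Path):
    """Return (accessions, label_names, probabilities, decided_mask)."""
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    header = lines[0].split("\t")
    label_names = [c[2:] for c in header if c.startswith("p:")]
    accs, probs, decided = [], [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        accs.append(parts[0])
        probs.append([float(x) for x in parts[1:1 + len(label_names)]])
        dec = set(parts[1 + len(label_names)].split(";")) - {""}
        decided.append([lab in dec for lab in label_names])
    return accs, label_names, np.array(probs), np.array(decided, dtype=bool)


def write_report_tsv(
    path: str | Path,
    report_all: EvaluationReport,
    report_ml: EvaluationReport | None,
    header_meta: dict | None = None,
) -> None:
    """Metric rows x {all, multilabel-only} columns."""
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("metric\tall_samples\tmultilabel_only\n")
        d_all = report_all.as_dict()
        d_ml = report_ml.as_dict() if report_ml else {}
        for metric, val in d_all.items():
            ml = f"{d_ml[metric]:.4f}" if metric in d_ml else "NA"
            fh.write(f"{metric}\t{val:.4f}\t{ml}\n")
        fh.write(
            f"n_samples\t{report_all.n_samples}\t"
            f"{report_ml.n_samples if report_ml else 'NA'}\n"
        )


def load_config(path: str | Path) -> dict:
    """YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
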