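"""File formats: HTK parameter files, MLF label files, lexicons, model
banks, corpora and run manifests.

The HTK feature dialect follows the classic parameter-file layout: a
12-byte big-endian header (nSamples int32, sampPeriod int32 in 100 ns
units, sampSize int16 in bytes, parmKind int16) followed by big-endian
float32 frames.  A portable text dialect (one whitespace-separated frame
per row) is provided for fully text-based pipelines.
"""

from __future__ import annotations

import hashlib
import json
import struct
from pathlib import Path

import numpy as np
import yaml

from .corpus import Corpus, Sentence
from .decoder import Grammar, Lexicon
from .hmm import GaussianMixtureEmission, ModelSet, PhoneHMM
from .topology import TopologySpec

HTK_PARM_USER = 9
DEFAULT_SAMP_PERIOD = 100000  # 10 ms in 100 ns units


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# feature files
# ---------------------------------------------------------------------------

def write_feature_file(
    path: str | Path,
    features: np.ndarray,
    dialect: str = "text",
    samp_period: int = DEFAULT_SAMP_PERIOD,
    parm_kind: int = HTK_PARM_USER,
) -> None:
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2:
        raise FormatError("features must be a 2-D (frames × dim) array")
    path = Path(path)
    if dialect == "text":
        np.savetxt(path, features, fmt="%.10g")
    elif dialect == "htk":
        n, d = features.shape
        header = struct.pack(">iihh", n, samp_period, 4 * d, parm_kind)
        path.write_bytes(
            header + features.astype(">f4").tobytes()
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_feature_file(path: str | Path, dialect: str = "text") -> np.ndarray:
    path = Path(path)
    if dialect == "text":
        data = np.loadtxt(path, ndmin=2)
        return data
    if dialect != "htk":
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = path.read_bytes()
    if len(raw) < 12:
        raise FormatError(f"{path}: truncated HTK header ({len(raw)} bytes)")
    n, samp_period, samp_size, parm_kind = struct.unpack(">iihh", raw[:12])
    if n < 0 or samp_size <= 0 or samp_size % 4:
        raise FormatError(
            f"{path}: malformed HTK header at offset 0 "
            f"(nSamples={n}, sampSize={samp_size})"
        )
    expected = 12 + n * samp_size
    if len(raw) != expected:
        raise FormatError(
            f"{path}: expected {expected} bytes, found {len(raw)} "
            f"(truncated at offset {len(raw)})"
        )
    d = samp_size // 4
    data = np.frombuffer(raw, dtype=">f4", offset=12).reshape(n, d)
    return data.astype(np.float64)


# ---------------------------------------------------------------------------
# MLF label files
# ---------------------------------------------------------------------------

def write_mlf(path: str | Path, transcripts: dict[str, list[str]]) -> None:
    lines = ["#!MLF!#"]
    for sent_id, labels in transcripts.items():
        lines.append(f'"*/{sent_id}.lab"')
        lines.extend(labels)
        lines.append(".")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mlf(path: str | Path) -> dict[str, list[str]]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "#!MLF!#":
        raise FormatError(f"{path}:1: missing #!MLF!# header")
    out: dict[str, list[str]] = {}
    current: str | None = None
    labels: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line:
            continue
        if line.startswith('"'):
            if current is not None:
                raise FormatError(
                    f"{path}:{lineno}: new entry before '.' terminator"
                )
            name = line.strip('"')
            sent_id = Path(name).stem
            if sent_id in out:
                raise FormatError(f"{path}:{lineno}: duplicate id {sent_id!r}")
            current = sent_id
            labels = []
        elif line == ".":
            if current is None:
                raise FormatError(f"{path}:{lineno}: '.' outside an entry")
            out[current] = labels
            current = None
        else:
            if current is None:
                raise FormatError(f"{path}:{lineno}: label outside an entry")
            labels.append(line.split()[-1] if " " in line else line)
    if current is not None:
        raise FormatError(f"{path}: unterminated entry {current!r}")
    return out


# ---------------------------------------------------------------------------
# lexicon and grammar
# ---------------------------------------------------------------------------

def write_lexicon(path: str | Path, lexicon: Lexicon) -> None:
    lines = [
        f"{word} {' '.join(phones)}"
        for word, phones in lexicon.entries.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_lexicon(path: str | Path) -> Lexicon:
    entries: dict[str, tuple[str, ...]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'WORD phone ...'")
        if parts[0] in entries:
            raise FormatError(f"{path}:{lineno}: duplicate word {parts[0]!r}")
        entries[parts[0]] = tuple(parts[1:])
    return Lexicon(entries)


def write_grammar(path: str | Path, grammar: Grammar) -> None:
    doc = {"kind": grammar.kind}
    if grammar.kind == "sentence_template":
        doc["slots"] = [list(s) for s in grammar.slots]
    else:
        doc["loop_words"] = list(grammar.loop_words)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_grammar(path: str | Path) -> Grammar:
    doc = yaml.safe_load(Path(path).read_text())
    return Grammar(
        kind=doc["kind"],
        slots=doc.get("slots", []),
        loop_words=doc.get("loop_words", []),
    )


# ---------------------------------------------------------------------------
# model bank serialization
# ---------------------------------------------------------------------------

MODEL_FORMAT = "phonotop-models"
MODEL_VERSION = 1


def model_set_to_dict(model_set: ModelSet) -> dict:
    return {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "feature_dim": model_set.feature_dim,
        "variance_floor": np.asarray(model_set.variance_floor).tolist(),
        "hmms": {
            label: {
                "topo_type": h.spec.topo_type,
                "n_states": h.spec.n_states,
                "trans": h.trans.tolist(),
                "emissions": [
                    {
                        "weights": e.weights.tolist(),
                        "means": e.means.tolist(),
                        "variances": e.variances.tolist(),
                    }
                    for e in h.emissions
                ],
            }
            for label, h in model_set.hmms.items()
        },
    }


def model_set_from_dict(doc: dict) -> ModelSet:
    if doc.get("format") != MODEL_FORMAT:
        raise FormatError("not a phonotop model document")
    if doc.get("version") != MODEL_VERSION:
        raise FormatError(f"unsupported model version {doc.get('version')!r}")
    hmms = {}
    for label, h in doc["hmms"].items():
        spec = TopologySpec(h["topo_type"], h["n_states"])
        emissions = [
            GaussianMixtureEmission(
                weights=np.asarray(e["weights"]),
                means=np.asarray(e["means"]),
                variances=np.asarray(e["variances"]),
            )
            for e in h["emissions"]
        ]
        hmms[label] = PhoneHMM(label, spec, np.asarray(h["trans"]), emissions)
    return ModelSet(
        hmms=hmms,
        feature_dim=doc["feature_dim"],
        variance_floor=np.asarray(doc["variance_floor"]),
    )


def save_model_set(path: str | Path, model_set: ModelSet) -> None:
    Path(path).write_text(json.dumps(model_set_to_dict(model_set)))


def load_model_set(path: str | Path) -> ModelSet:
    return model_set_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# corpus directories
# ---------------------------------------------------------------------------

def save_corpus(
    directory: str | Path, corpus: Corpus, dialect: str = "text"
) -> None:
    """Corpus as a directory: per-sentence feature files, word- and
    phone-level MLFs and a splits CSV."""
    directory = Path(directory)
    feat_dir = directory / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    ext = "txt" if dialect == "text" else "htk"
    words, phones, split_rows = {}, {}, []
    for i, sent in enumerate(corpus):
        sid = sent.sent_id or f"s{i + 1:04d}"
        write_feature_file(feat_dir / f"{sid}.{ext}", sent.features, dialect)
        words[sid] = list(sent.words)
        phones[sid] = list(sent.phones)
        split_rows.append(f"{sid},{sent.split}")
    write_mlf(directory / "words.mlf", words)
    write_mlf(directory / "phones.mlf", phones)
    (directory / "splits.csv").write_text(
        "sent_id,split\n" + "\n".join(split_rows) + "\n"
    )


def load_corpus(directory: str | Path, dialect: str = "text") -> Corpus:
    directory = Path(directory)
    words = read_mlf(directory / "words.mlf")
    phones = read_mlf(directory / "phones.mlf")
    splits = {}
    for line in (directory / "splits.csv").read_text().splitlines()[1:]:
        sid, split = line.split(",")
        splits[sid] = split
    ext = "txt" if dialect == "text" else "htk"
    sentences = []
    for sid in words:
        features = read_feature_file(
            directory / "features" / f"{sid}.{ext}", dialect
        )
        sentences.append(
            Sentence(
                features=features,
                words=tuple(words[sid]),
                phones=tuple(phones.get(sid, ())),
                split=splits.get(sid, ""),
                sent_id=sid,
            )
        )
    return Corpus(sentences)


# ---------------------------------------------------------------------------
# configuration and manifests
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return doc


def write_manifest(
    directory: str | Path, config: dict, seed: int
) -> None:
    """Run manifest alongside outputs: config hash, seed, versions."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "phonotop_version": __version__,
        "numpy_version": np.__version__,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
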