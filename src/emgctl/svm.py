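"""Embedded-style multiclass SVM: packed model, prediction, training.

The deployed classifier is a one-vs-one soft-margin SVM with an RBF kernel
``K(x, s) = exp(-gamma * ||x - s||^2)`` operating directly on the
4-dimensional EMG envelope vector (no feature extraction).  For each class
pair (j, k), j < k, the binary decision function is

    f(x) = sum_i C_i * K(x, s_i) - rho_{jk}

over the support vectors of the two classes, where the coefficients
``C_i = y_i * alpha_i`` (class label times support value) are pre-computed
at training time and stored alongside the support vectors in a compact,
statically laid-out memory image, exactly as an MCU flash sector would hold
them.  ``f(x) > 0`` votes for class j, otherwise class k; the predicted
gesture is the class with the most pairwise votes.

Margin optimization itself is delegated to scikit-learn's libSVM binding;
this module owns the packed representation, the prediction path, the
byte-level serialization and the memory-footprint accounting.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .gestures import Gesture, validate_mode

#: Fixed serialized header size in bytes (format tag and configuration).
HEADER_BYTES = 20
#: Bytes per per-class bookkeeping entry (label id u16 + SV count u16).
CLASS_ENTRY_BYTES = 4
_MAGIC = b"ESVM"
_FORMAT_VERSION = 1
_SVM_TYPE_RBF_OVO = 1
_HEADER_STRUCT = struct.Struct("<4sBBHHfI2x")  # magic, ver, type, NF, NCl, gamma, NS, pad
assert _HEADER_STRUCT.size == HEADER_BYTES


def rbf_kernel(x, s, gamma: float) -> float:
    """Radial basis kernel ``exp(-gamma * ||x - s||^2)``.

    Always in (0, 1] for finite inputs; equals 1 iff ``x == s``.
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    if x.shape != s.shape:
        raise ValueError(f"feature length mismatch: {x.shape} vs {s.shape}")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    d = x - s
    return float(np.exp(-gamma * np.dot(d, d)))


@dataclass
class SvmModel:
    """Packed one-vs-one SVM model mirroring the flash memory layout.

    Attributes
    ----------
    n_features, n_classes
        Input dimensionality NF and number of gesture classes NCl.
    gamma
        RBF kernel parameter (stored single precision).
    class_labels
        The NCl gesture ids, ascending; position = class index.
    sv_counts
        Support vectors per class; SV rows are grouped by class in this
        order, so each pair's SV set is two contiguous blocks.
    support_vectors
        (NS, NF) float32 — the s_i.
    coefficients
        (NS, NCl-1) float32 pre-computed C_i = y_i * alpha_i in the libSVM
        per-class column convention: for pair (j, k) the active columns are
        ``k - 1`` over class-j rows and ``j`` over class-k rows.
    rho
        NCl*(NCl-1)/2 offsets, one per pair (j, k), j < k, in
        lexicographic pair order.
    """

    n_features: int
    n_classes: int
    gamma: float
    class_labels: list
    sv_counts: np.ndarray
    support_vectors: np.ndarray
    coefficients: np.ndarray
    rho: np.ndarray

    def __post_init__(self):
        self.gamma = float(np.float32(self.gamma))
        self.class_labels = [Gesture(c) for c in self.class_labels]
        self.sv_counts = np.asarray(self.sv_counts, dtype=np.int64)
        self.support_vectors = np.asarray(self.support_vectors, dtype=np.float32)
        self.coefficients = np.asarray(self.coefficients, dtype=np.float32)
        self.rho = np.asarray(self.rho, dtype=np.float32)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        ncl, nf, ns = self.n_classes, self.n_features, self.n_sv
        if ncl < 2:
            raise ValueError("model needs at least 2 classes")
        if len(self.class_labels) != ncl:
            raise ValueError("class_labels length != n_classes")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if ns < 1:
            raise ValueError("model needs at least one support vector")
        if self.sv_counts.shape != (ncl,) or np.any(self.sv_counts < 0):
            raise ValueError("bad sv_counts")
        if int(self.sv_counts.sum()) != ns:
            raise ValueError("sv_counts do not sum to the SV row count")
        if self.support_vectors.shape != (ns, nf):
            raise ValueError("support_vectors shape mismatch")
        if self.coefficients.shape != (ns, ncl - 1):
            raise ValueError("coefficients shape mismatch")
        if self.rho.shape != (self.n_pairs,):
            raise ValueError("rho length != number of class pairs")

    @property
    def n_sv(self) -> int:
        return len(self.support_vectors)

    @property
    def n_pairs(self) -> int:
        return self.n_classes * (self.n_classes - 1) // 2

    def class_slice(self, idx: int) -> slice:
        """Row slice of class ``idx``'s contiguous SV block."""
        starts = np.concatenate([[0], np.cumsum(self.sv_counts)])
        return slice(int(starts[idx]), int(starts[idx + 1]))

    def pair_index(self, j: int, k: int) -> int:
        """Lexicographic index of pair (j, k), j < k, into ``rho``."""
        ncl = self.n_classes
        if not (0 <= j < k < ncl):
            raise ValueError(f"invalid class pair ({j}, {k}) for NCl={ncl}")
        return j * (2 * ncl - j - 1) // 2 + (k - j - 1)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SvmModel):
            return NotImplemented
        return (
            self.n_features == other.n_features
            and self.n_classes == other.n_classes
            and np.float32(self.gamma) == np.float32(other.gamma)
            and self.class_labels == other.class_labels
            and np.array_equal(self.sv_counts, other.sv_counts)
            and np.array_equal(self.support_vectors, other.support_vectors)
            and np.array_equal(self.coefficients, other.coefficients)
            and np.array_equal(self.rho, other.rho)
        )


def _kernel_row(model: SvmModel, x: np.ndarray) -> np.ndarray:
    """K(x, s_i) for every stored SV, float64 accumulation."""
    sv = model.support_vectors.astype(np.float64)
    d = sv - np.asarray(x, dtype=np.float64)[None, :]
    return np.exp(-model.gamma * np.einsum("ij,ij->i", d, d))


def pair_decision(x, model: SvmModel, pair) -> float:
    """Binary decision value f(x) for one class pair (j, k), j < k.

    Positive f votes for class j, negative for class k.
    """
    j, k = pair
    p = model.pair_index(j, k)
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_features,):
        raise ValueError(
            f"input has {x.shape} features, model expects {model.n_features}"
        )
    kern = _kernel_row(model, x)
    sj, sk = model.class_slice(j), model.class_slice(k)
    coef = model.coefficients.astype(np.float64)
    f = (
        np.dot(coef[sj, k - 1], kern[sj])
        + np.dot(coef[sk, j], kern[sk])
        - float(model.rho[p])
    )
    return float(f)


def vote_vector(x, model: SvmModel) -> np.ndarray:
    """Pairwise vote counts v over all class pairs (sums to NCl(NCl-1)/2)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_features,):
        raise ValueError(
            f"input has {x.shape} features, model expects {model.n_features}"
        )
    kern = _kernel_row(model, x)
    coef = model.coefficients.astype(np.float64)
    ncl = model.n_classes
    v = np.zeros(ncl, dtype=int)
    for j in range(ncl):
        sj = model.class_slice(j)
        for k in range(j + 1, ncl):
            sk = model.class_slice(k)
            f = (
                np.dot(coef[sj, k - 1], kern[sj])
                + np.dot(coef[sk, j], kern[sk])
                - float(model.rho[model.pair_index(j, k)])
            )
            if f > 0:
                v[j] += 1
            else:  # f == 0 counts for the second class, consistent with
                v[k] += 1  # f > 0 belonging to the first class
    return v


def svm_predict(x, model: SvmModel) -> Gesture:
    """Predict the gesture of one envelope frame.

    Runs every pairwise decision, tallies votes and returns the label with
    the most; vote ties resolve to the lowest class index (argmax of the
    vote vector, stable).
    """
    v = vote_vector(x, model)
    return model.class_labels[int(np.argmax(v))]


def svm_predict_batch(X, model: SvmModel) -> list:
    """Vectorised :func:`svm_predict` over rows of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise ValueError("feature count mismatch")
    sv = model.support_vectors.astype(np.float64)
    sq = ((X[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
    kern = np.exp(-model.gamma * sq)  # (n, NS)
    coef = model.coefficients.astype(np.float64)
    ncl = model.n_classes
    votes = np.zeros((len(X), ncl), dtype=int)
    for j in range(ncl):
        sj = model.class_slice(j)
        for k in range(j + 1, ncl):
            sk = model.class_slice(k)
            f = (
                kern[:, sj] @ coef[sj, k - 1]
                + kern[:, sk] @ coef[sk, j]
                - float(model.rho[model.pair_index(j, k)])
            )
            pos = f > 0
            votes[pos, j] += 1
            votes[~pos, k] += 1
    idx = votes.argmax(axis=1)
    return [model.class_labels[i] for i in idx]


# ---------------------------------------------------------------------------
# Training front-end


class EmbeddedSVC(BaseEstimator, ClassifierMixin):
    """Scikit-learn style trainer producing a packed :class:`SvmModel`.

    ``fit`` delegates margin optimization to :class:`sklearn.svm.SVC`
    (RBF kernel, one-vs-one) and repacks the solver output — support
    vectors, pre-computed C_i = y_i * alpha_i coefficients and pair
    offsets — into the static flash-image layout used on the wearable
    node.  ``predict`` runs the packed prediction path, not the solver's.

    Parameters
    ----------
    c : float, default 1.0
        Soft-margin regularization.
    gamma : float or "scale_nf", default "scale_nf"
        RBF kernel parameter; ``"scale_nf"`` uses 1 / NF.
    mode : {"COMPLETE", "REDUCED"}, default "COMPLETE"
        REDUCED models must be trained without the open-hand class.

    Attributes
    ----------
    model_ : SvmModel
        The packed model.
    classes_ : ndarray
        Sorted class labels seen during fit.
    """

    def __init__(self, c: float = 1.0, gamma="scale_nf", mode: str = "COMPLETE"):
        self.c = c
        self.gamma = gamma
        self.mode = mode

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        mode = validate_mode(self.mode)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain at least 2 classes")
        if mode == "REDUCED" and int(Gesture.OPEN_HAND) in classes:
            raise ValueError("REDUCED models exclude the open-hand gesture")
        nf = X.shape[1]
        gamma = 1.0 / nf if self.gamma == "scale_nf" else float(self.gamma)
        svc = SVC(C=self.c, kernel="rbf", gamma=gamma,
                  decision_function_shape="ovo")
        svc.fit(X, y)
        self.solver_ = svc
        self.classes_ = svc.classes_
        self.model_ = pack_solver(svc, nf, gamma)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return np.asarray([int(g) for g in svm_predict_batch(X, self.model_)])


def pack_solver(svc: SVC, n_features: int, gamma: float) -> SvmModel:
    """Repack a fitted sklearn ovo SVC into the static model layout.

    libSVM's dual coefficients arrive as (NCl-1, NS); stored transposed so
    each SV row carries its NCl-1 pre-computed C_i values.  libSVM's rho
    equals ``-intercept_``, matching the f(x) = sum - rho convention.

    With exactly two classes sklearn negates the raw libSVM decision so
    that positive values mean ``classes_[1]``; the packed layout keeps the
    one convention f(x) > 0 -> first class of the pair, so the binary
    coefficients and offset are negated back.
    """
    coef = svc.dual_coef_.T.astype(np.float64)
    rho = -svc.intercept_.astype(np.float64)
    if len(svc.classes_) == 2:
        coef = -coef
        rho = -rho
    return SvmModel(
        n_features=n_features,
        n_classes=len(svc.classes_),
        gamma=gamma,
        class_labels=[Gesture(int(c)) for c in svc.classes_],
        sv_counts=svc.n_support_.astype(np.int64),
        support_vectors=svc.support_vectors_.astype(np.float32),
        coefficients=coef.astype(np.float32),
        rho=np.asarray(rho, dtype=np.float32),
    )


def train_model(X, y, gamma="scale_nf", c: float = 1.0,
                mode: str = "COMPLETE") -> SvmModel:
    """Train and pack a model (functional wrapper over :class:`EmbeddedSVC`)."""
    return EmbeddedSVC(c=c, gamma=gamma, mode=mode).fit(X, y).model_


# ---------------------------------------------------------------------------
# Memory footprint and byte-level serialization


def model_footprint_bytes(model_or_shape, dtype_size: int = 4,
                          int_size: int = CLASS_ENTRY_BYTES) -> int:
    """Static memory footprint of a packed model.

    ``20 + dtype_size * (NS*NF + NS*(NCl-1) + NCl*(NCl-1)/2) + NCl*int_size``
    — the fixed 20-byte header, the value payload (SVs, pre-computed
    coefficients, pair offsets) at the storage precision, and the per-class
    SV bookkeeping.  Accepts an :class:`SvmModel` or an ``(NS, NF, NCl)``
    shape tuple (``NS = 0`` degenerates to header + bookkeeping only).
    """
    if dtype_size not in (4, 8):
        raise ValueError("dtype_size must be 4 or 8 bytes")
    if isinstance(model_or_shape, SvmModel):
        ns, nf, ncl = (model_or_shape.n_sv, model_or_shape.n_features,
                       model_or_shape.n_classes)
    else:
        ns, nf, ncl = model_or_shape
    npairs = ncl * (ncl - 1) // 2
    return HEADER_BYTES + dtype_size * (ns * nf + ns * (ncl - 1) + npairs) + ncl * int_size


class ModelFormatError(ValueError):
    """Raised when a serialized model image is malformed."""


def serialize_model(model: SvmModel) -> bytes:
    """Serialize to the flash-image byte layout.

    Header (20 B: magic, version, SVM type, NF, NCl, gamma, NS), then the
    per-class table (label id u16 + SV count u16 each), then the rho block,
    then the contiguous SV block, then the contiguous coefficient block —
    all values little-endian IEEE-754 single precision.  The total length
    equals ``model_footprint_bytes(model, 4)``.
    """
    head = _HEADER_STRUCT.pack(_MAGIC, _FORMAT_VERSION, _SVM_TYPE_RBF_OVO,
                               model.n_features, model.n_classes,
                               np.float32(model.gamma), model.n_sv)
    parts = [head]
    for lab, cnt in zip(model.class_labels, model.sv_counts):
        parts.append(struct.pack("<HH", int(lab), int(cnt)))
    parts.append(np.asarray(model.rho, "<f4").tobytes())
    parts.append(np.ascontiguousarray(model.support_vectors, "<f4").tobytes())
    parts.append(np.ascontiguousarray(model.coefficients, "<f4").tobytes())
    return b"".join(parts)


def deserialize_model(blob: bytes) -> SvmModel:
    """Parse a flash-image byte string back into an :class:`SvmModel`."""
    if len(blob) < HEADER_BYTES:
        raise ModelFormatError("truncated header")
    magic, ver, svmtype, nf, ncl, gamma, ns = _HEADER_STRUCT.unpack_from(blob)
    if magic != _MAGIC:
        raise ModelFormatError(f"bad magic {magic!r} in header")
    if ver != _FORMAT_VERSION or svmtype != _SVM_TYPE_RBF_OVO:
        raise ModelFormatError("unsupported format version or SVM type in header")
    npairs = ncl * (ncl - 1) // 2
    expect = model_footprint_bytes((ns, nf, ncl), 4)
    if len(blob) != expect:
        raise ModelFormatError(
            f"payload length {len(blob)} != expected {expect} "
            "(truncated or trailing bytes)"
        )
    off = HEADER_BYTES
    labels, counts = [], []
    for _ in range(ncl):
        lab, cnt = struct.unpack_from("<HH", blob, off)
        labels.append(lab)
        counts.append(cnt)
        off += CLASS_ENTRY_BYTES
    if sum(counts) != ns:
        raise ModelFormatError("per-class SV counts do not sum to NS")
    rho = np.frombuffer(blob, "<f4", npairs, off)
    off += 4 * npairs
    sv = np.frombuffer(blob, "<f4", ns * nf, off).reshape(ns, nf)
    off += 4 * ns * nf
    coef = np.frombuffer(blob, "<f4", ns * (ncl - 1), off).reshape(ns, ncl - 1)
    try:
        return SvmModel(nf, ncl, gamma, labels, np.asarray(counts),
                        sv.copy(), coef.copy(), rho.copy())
    except ValueError as exc:
        raise ModelFormatError(f"inconsistent model payload: {exc}") from exc


def save_model(model: SvmModel, path) -> None:
    with open(path, "wb") as fh:
        fh.write(serialize_model(model))


def load_model(path) -> SvmModel:
    with open(path, "rb") as fh:
        return deserialize_model(fh.read())
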