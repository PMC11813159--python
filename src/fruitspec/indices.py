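"""Two-band spectral reflectance indices (SRIs).

The library of sixteen indices combines four widely used published indices
(GI, PSRMI, NAI, NDVI) with twelve two-band ratio indices R_l1/R_l2 tuned to
fruit-ripening spectral features: a red-region block (666/636, 660/620,
670/610, 618/602, 640/590, 970/590) sensitive to chlorophyll/anthocyanin
changes, and an NIR block (764/766, 768/770, 772/762, 766/764, 760/858,
970/1000) sensitive to fine NIR shape and water features.

All formulas are ratios of linear band combinations, so every index is
invariant under a global multiplicative rescaling of a sample's spectrum
(illumination level), the property that makes SRIs usable outdoors.
"""

from __future__ import annotations

import ast
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import SpectraSet, WavelengthGrid, reflectance_at

__all__ = [
    "IndexDefinition",
    "IndexValues",
    "registry",
    "registry_names",
    "get_index",
    "compute_rsi",
    "compute_published",
    "compute_index",
    "index_table",
    "export_index_values",
    "parse_index_formula",
    "SpectralIndexTransformer",
    "NEW_RATIO_PAIRS",
]

#: The twelve newly constructed ratio pairs (numerator nm, denominator nm).
NEW_RATIO_PAIRS: tuple[tuple[float, float], ...] = (
    (666, 636), (660, 620), (670, 610), (618, 602), (640, 590), (970, 590),
    (764, 766), (768, 770), (772, 762), (766, 764), (760, 858), (970, 1000),
)

_WAVELENGTH_SPAN = (302.0, 1148.0)


@dataclass(frozen=True)
class IndexDefinition:
    """A named spectral index formula over reflectance bands.

    ``family`` is ``"ratio"`` (R_l1/R_l2), ``"normalized_difference"``
    ((R_l1 - R_l2)/(R_l1 + R_l2)) or ``"custom"`` (arbitrary expression over
    ``R<nm>`` symbols evaluated through a restricted grammar).
    """

    name: str
    family: str
    wavelengths: tuple[float, ...]
    formula: str
    _func: Callable[[SpectraSet], np.ndarray] | None = field(
        default=None, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        if self.family not in ("ratio", "normalized_difference", "custom"):
            raise ValueError(f"unknown index family {self.family!r}")
        if self.family in ("ratio", "normalized_difference") and len(self.wavelengths) != 2:
            raise ValueError(f"{self.family} index needs exactly 2 wavelengths")
        for nm in self.wavelengths:
            if not (_WAVELENGTH_SPAN[0] <= nm <= _WAVELENGTH_SPAN[1]):
                raise ValueError(f"wavelength {nm} nm outside {_WAVELENGTH_SPAN}")

    def evaluate(self, s: SpectraSet) -> np.ndarray:
        if self.family == "ratio":
            a, b = self.wavelengths
            return _safe_ratio(reflectance_at(s, a), reflectance_at(s, b), self.name)
        if self.family == "normalized_difference":
            a, b = self.wavelengths
            ra, rb = reflectance_at(s, a), reflectance_at(s, b)
            return _safe_ratio(ra - rb, ra + rb, self.name)
        if self._func is not None:
            return self._func(s)
        return parse_index_formula(self.formula)(s)


@dataclass
class IndexValues:
    """Per-sample evaluation of one index."""

    index: IndexDefinition
    sample_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "index_name": self.index.name,
            "value": self.values,
        })


def _safe_ratio(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    if np.any(~np.isfinite(out)):
        warnings.warn(f"index {name}: zero denominator produced non-finite values",
                      stacklevel=3)
    return out


# ---------------------------------------------------------------------------
# Safe expression grammar for custom formulas: R<nm> symbols, numbers, + - * / ()
# ---------------------------------------------------------------------------

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div)


def parse_index_formula(expr: str) -> Callable[[SpectraSet], np.ndarray]:
    """Compile a custom index expression over ``R<nm>`` band symbols.

    Only arithmetic (+ - * /), parentheses, numeric literals and band symbols
    like ``R677`` or ``R760.5`` are accepted; anything else (names, calls,
    attributes) is rejected, so formulas from config files cannot execute code.
    """
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise ValueError(f"invalid index formula {expr!r}: {exc}") from exc

    bands: list[float] = []

    def check(node: ast.AST) -> None:
        if isinstance(node, ast.Expression):
            check(node.body)
        elif isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
            check(node.left)
            check(node.right)
        elif isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
            check(node.operand)
        elif isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
            pass
        elif isinstance(node, ast.Name):
            if not node.id.startswith("R") or not _is_number(node.id[1:]):
                raise ValueError(f"unknown symbol {node.id!r} in index formula")
            bands.append(float(node.id[1:]))
        else:
            raise ValueError(
                f"disallowed construct {type(node).__name__} in index formula {expr!r}"
            )

    check(tree)
    code = compile(tree, "<index formula>", "eval")

    def evaluate(s: SpectraSet) -> np.ndarray:
        env = {f"R{nm:g}": reflectance_at(s, nm) for nm in bands}
        # also allow the verbatim spelling used in the formula (e.g. R760.0)
        for node in ast.walk(tree):
            if isinstance(node, ast.Name):
                env.setdefault(node.id, reflectance_at(s, float(node.id[1:])))
        with np.errstate(divide="ignore", invalid="ignore"):
            out = eval(code, {"__builtins__": {}}, env)  # noqa: S307 - grammar-checked
        out = np.asarray(out, dtype=float)
        if np.any(~np.isfinite(out)):
            warnings.warn("custom index produced non-finite values", stacklevel=2)
        return out

    return evaluate


def _is_number(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# Registry of the sixteen library indices
# ---------------------------------------------------------------------------

def _published_definitions() -> list[IndexDefinition]:
    return [
        IndexDefinition("GI", "ratio", (554, 677), "R554/R677"),
        IndexDefinition(
            "PSRMI", "custom", (750, 678, 550), "(R750 - R678)/R550",
            _func=lambda s: _safe_ratio(
                reflectance_at(s, 750) - reflectance_at(s, 678),
                reflectance_at(s, 550), "PSRMI"),
        ),
        IndexDefinition("NAI", "normalized_difference", (760, 720),
                        "(R760 - R720)/(R760 + R720)"),
        IndexDefinition("NDVI", "normalized_difference", (780, 670),
                        "(R780 - R670)/(R780 + R670)"),
    ]


def rsi_name(l1: float, l2: float) -> str:
    return f"RSI_{l1:g},{l2:g}"


def registry() -> list[IndexDefinition]:
    """All sixteen library index definitions: 4 published + 12 new ratios."""
    defs = _published_definitions()
    for l1, l2 in NEW_RATIO_PAIRS:
        defs.append(IndexDefinition(rsi_name(l1, l2), "ratio", (l1, l2),
                                    f"R{l1:g}/R{l2:g}"))
    return defs


def registry_names() -> list[str]:
    return [d.name for d in registry()]

#: Alternate spellings accepted by name lookup (PRMI appears in some tables).
_ALIASES = {"PRMI": "PSRMI", "NDVI_780,670": "NDVI"}


def get_index(name: str) -> IndexDefinition:
    canonical = _ALIASES.get(name, name)
    for d in registry():
        if d.name == canonical:
            return d
    raise KeyError(f"unknown index {name!r}; registered: {registry_names()}")


def compute_rsi(s: SpectraSet, l1: float, l2: float) -> IndexValues:
    """Two-band ratio index R_l1 / R_l2 per sample (Eq. RSI = R1/R2)."""
    d = IndexDefinition(rsi_name(l1, l2), "ratio", (l1, l2), f"R{l1:g}/R{l2:g}")
    return IndexValues(d, list(s.sample_ids), d.evaluate(s))


def compute_published(s: SpectraSet, name: str) -> IndexValues:
    """Evaluate a registered published index by name."""
    try:
        d = get_index(name)
    except KeyError as exc:
        raise KeyError(str(exc)) from None
    return IndexValues(d, list(s.sample_ids), d.evaluate(s))


def compute_index(s: SpectraSet, definition: IndexDefinition) -> IndexValues:
    return IndexValues(definition, list(s.sample_ids), definition.evaluate(s))


def index_table(s: SpectraSet, definitions: Sequence[IndexDefinition] | None = None
                ) -> pd.DataFrame:
    """Sample x index matrix for a set of definitions (default: full registry)."""
    defs = list(definitions) if definitions is not None else registry()
    data = {d.name: d.evaluate(s) for d in defs}
    return pd.DataFrame(data, index=pd.Index(s.sample_ids, name="sample_id"))


def export_index_values(values: Sequence[IndexValues], path, delimiter: str = ",") -> None:
    """Tidy export: one row per (sample_id, index_name, value)."""
    frames = [v.to_frame() for v in values]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=delimiter, index=False)


class SpectralIndexTransformer(TransformerMixin, BaseEstimator):
    """Transform reflectance spectra into spectral-index features.

    Works on plain ``(n_samples, n_bands)`` arrays so it composes with
    sklearn pipelines; the ``wavelengths`` parameter gives the meaning of the
    input columns.

    Parameters
    ----------
    wavelengths : array-like
        Wavelength (nm) of each input column.
    indices : sequence of str or IndexDefinition, optional
        Which indices to compute; default is the full 16-index registry.
    """

    def __init__(self, wavelengths=None, indices=None):
        self.wavelengths = wavelengths
        self.indices = indices

    def _definitions(self) -> list[IndexDefinition]:
        if self.indices is None:
            return registry()
        defs = []
        for item in self.indices:
            defs.append(item if isinstance(item, IndexDefinition) else get_index(item))
        return defs

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.wavelengths is None:
            raise ValueError("wavelengths must be provided to interpret columns")
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.size != X.shape[1]:
            raise ValueError("wavelengths length must equal number of columns")
        self.grid_ = WavelengthGrid(wl)
        self.definitions_ = self._definitions()
        self.feature_names_out_ = [d.name for d in self.definitions_]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "definitions_"):
            raise ValueError("SpectralIndexTransformer is not fitted")
        X = np.asarray(X, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
        s = SpectraSet(grid=self.grid_, reflectance=X, sample_ids=ids)
        return np.column_stack([d.evaluate(s) for d in self.definitions_])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)
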