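"""End-to-end conversion pipeline: logfile text -> compchem document.

Chains the stages: template matching (chunk recognition and record capture),
per-template declarative transforms, convention restructuring, and
dictionary/convention validation.  The shipped Gaussian template pack and
role rules live in package data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .compchem import RestructureRules, restructure, validate_convention
from .dictionary import (Dictionary, ValidationReport,
                         load_compchem_dictionary, validate_refs)
from .semdoc import SemNode
from .template_engine import ParseResult, Template, load_templates, match_chunks

__all__ = ["ConversionResult", "load_gaussian_pack", "load_gaussian_rules",
           "convert_text", "load_ch4_document"]


def load_ch4_document() -> SemNode:
    """The reference two-job CH4 compchem document shipped as package data."""
    from .semdoc import read_document
    text = resources.files("cclog.data").joinpath("ch4.cml.xml").read_text()
    return read_document(text)


@dataclass
class ConversionResult:
    document: SemNode          # compchem-convention document
    raw: SemNode               # raw chunk-ordered parse
    parse: ParseResult         # chunks + unparsed residue
    convention: ValidationReport
    dictionary: ValidationReport


def load_gaussian_pack() -> list[Template]:
    """The demonstrative Gaussian template pack shipped as package data."""
    text = resources.files("cclog.data").joinpath("gaussian_pack.xml").read_text()
    return load_templates(text)


def load_gaussian_rules() -> RestructureRules:
    text = resources.files("cclog.data").joinpath("gaussian_roles.txt").read_text()
    return RestructureRules.from_text(text)


def convert_text(text: str,
                 templates: list[Template] | None = None,
                 rules: RestructureRules | None = None,
                 dictionaries: list[Dictionary] | None = None) -> ConversionResult:
    """Parse, transform, restructure and validate one logfile."""
    if templates is None:
        templates = load_gaussian_pack()
    if rules is None:
        rules = load_gaussian_rules()
    if dictionaries is None:
        dictionaries = [load_compchem_dictionary()]
    parse = match_chunks(text, templates)
    doc = restructure(parse.document, rules)
    return ConversionResult(
        document=doc,
        raw=parse.document,
        parse=parse,
        convention=validate_convention(doc),
        dictionary=validate_refs(doc, dictionaries),
    )
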