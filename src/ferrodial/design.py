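"""Experimental layout of a dialyzability study.

The study design couples a catalog of iron preparations (chemical form,
dose, pharmaceutical form) with a set of whole-day diet models and a
replication scheme: every product is digested in every diet, in
``n_batches`` independent product batches with ``n_replicates`` digestions
each; every diet is additionally digested alone (one batch); and a small
number of reagent blanks run through the same protocol.  Each digestion
yields two analyzable fractions — the dialysate that crossed the cellulose
membrane and the retentate left inside the tube — so the analytical sample
count is twice the digestion count, plus reference-material replicates
used for method validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence


class ChemicalForm(str, Enum):
    FUMARATE = "fumarate"
    LACTATE = "lactate"
    SULFATE = "sulfate"
    BISGLYCINATE = "bisglycinate"
    GLUCONATE = "gluconate"


class PharmaForm(str, Enum):
    COATED_TABLET = "coated_tablet"
    TABLET = "tablet"
    EXTENDED_RELEASE_TABLET = "extended_release_tablet"
    CAPSULE = "capsule"


class Diet(str, Enum):
    STANDARD = "standard"
    BASIC = "basic"
    HIGH_RESIDUE = "high_residue"


class Fraction(str, Enum):
    DIALYSATE = "dialysate"
    RETENTATE = "retentate"


@dataclass(frozen=True)
class Product:
    """One iron preparation: a coded product with its label metadata."""

    product_id: int
    chemical_form: ChemicalForm
    iron_dose: float  # mg elemental iron per unit dose
    pharma_form: PharmaForm
    product_type: str = "supplement"

    def __post_init__(self) -> None:
        if not self.iron_dose > 0:
            raise ValueError(f"iron_dose must be > 0, got {self.iron_dose}")


#: The default catalog of eight coded preparations: six supplements, one
#: OTC drug (product 7) and one prescription drug (product 8).
PRODUCT_CATALOG: tuple[Product, ...] = (
    Product(1, ChemicalForm.FUMARATE, 14.0, PharmaForm.COATED_TABLET,
            "vitamin-mineral with plant extracts supplement"),
    Product(2, ChemicalForm.LACTATE, 9.9, PharmaForm.COATED_TABLET,
            "vitamin-mineral with plant extracts supplement"),
    Product(3, ChemicalForm.FUMARATE, 14.0, PharmaForm.TABLET,
            "vitamin-mineral supplement"),
    Product(4, ChemicalForm.SULFATE, 9.9, PharmaForm.COATED_TABLET,
            "vitamin-mineral supplement"),
    Product(5, ChemicalForm.FUMARATE, 12.0, PharmaForm.TABLET,
            "vitamin-mineral with plant extracts supplement"),
    Product(6, ChemicalForm.BISGLYCINATE, 14.0, PharmaForm.CAPSULE,
            "single mineral supplement"),
    Product(7, ChemicalForm.GLUCONATE, 23.2, PharmaForm.COATED_TABLET,
            "OTC drug"),
    Product(8, ChemicalForm.SULFATE, 105.0, PharmaForm.EXTENDED_RELEASE_TABLET,
            "prescription drug"),
)


@dataclass(frozen=True)
class StudyDesign:
    products: tuple[Product, ...]
    diets: tuple[Diet, ...]
    n_batches: int = 3
    n_replicates: int = 3
    n_blanks: int = 3
    n_reference_reps: int = 6
    fractions_per_digestion: int = 2

    def __post_init__(self) -> None:
        if not self.products:
            raise ValueError("design requires at least one product")
        if not self.diets:
            raise ValueError("design requires at least one diet")
        ids = [p.product_id for p in self.products]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate product_id in {ids}")
        if len(set(self.diets)) != len(self.diets):
            raise ValueError("duplicate diet in design")
        for name in ("n_batches", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_blanks", "n_reference_reps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def product(self, product_id: int) -> Product:
        for p in self.products:
            if p.product_id == product_id:
                return p
        raise KeyError(f"unknown product_id {product_id}")


@dataclass(frozen=True)
class SampleCounts:
    n_models: int
    n_digestion_samples: int
    n_analytical_samples: int
    n_total_with_reference: int


@dataclass(frozen=True)
class SampleID:
    """Identity of one analytical sample (one fraction of one digestion).

    ``product_id`` is ``None`` for diet-only models and blanks; ``diet`` is
    ``None`` only for blanks.  Diet-only models run as a single batch.
    """

    product_id: Optional[int]
    diet: Optional[Diet]
    batch: int
    replicate: int
    fraction: Fraction

    @property
    def is_blank(self) -> bool:
        return self.diet is None

    @property
    def is_diet_only(self) -> bool:
        return self.diet is not None and self.product_id is None

    def digestion_key(self) -> tuple:
        """Identity of the parent digestion (fraction stripped)."""
        return (self.product_id, self.diet, self.batch, self.replicate)


def build_design(products: Sequence[Product],
                 diets: Sequence[Diet],
                 n_batches: int = 3,
                 n_replicates: int = 3,
                 n_blanks: int = 3,
                 n_reference_reps: int = 6) -> StudyDesign:
    """Validate and assemble a study design."""
    return StudyDesign(tuple(products), tuple(diets), n_batches,
                       n_replicates, n_blanks, n_reference_reps)


def default_design() -> StudyDesign:
    """The full study layout: 8 products x 3 diets x 3 batches x 3
    replicates, 3 diet-only models x 3 replicates, 3 blanks, 6 reference
    replicates."""
    return build_design(PRODUCT_CATALOG, tuple(Diet))


def enumerate_samples(design: StudyDesign) -> SampleCounts:
    """Count models and samples implied by a design.

    Models are product x diet combinations plus one diet-only model per
    diet.  Digestions are products x diets x batches x replicates, plus
    diet-only replicates (single batch), plus blanks; every digestion
    yields ``fractions_per_digestion`` analytical samples.
    """
    n_products = len(design.products)
    n_diets = len(design.diets)
    n_models = n_products * n_diets + n_diets
    n_digestion = (n_products * n_diets * design.n_batches * design.n_replicates
                   + n_diets * design.n_replicates
                   + design.n_blanks)
    n_analytical = n_digestion * design.fractions_per_digestion
    return SampleCounts(
        n_models=n_models,
        n_digestion_samples=n_digestion,
        n_analytical_samples=n_analytical,
        n_total_with_reference=n_analytical + design.n_reference_reps,
    )


def expand_inventory(design: StudyDesign) -> list[SampleID]:
    """One :class:`SampleID` per analytical sample, in deterministic order:
    product models, then diet-only models, then blanks; fractions innermost."""
    fractions = (Fraction.DIALYSATE, Fraction.RETENTATE)
    out: list[SampleID] = []
    for p in design.products:
        for d in design.diets:
            for b in range(1, design.n_batches + 1):
                for r in range(1, design.n_replicates + 1):
                    for f in fractions:
                        out.append(SampleID(p.product_id, d, b, r, f))
    for d in design.diets:
        for r in range(1, design.n_replicates + 1):
            for f in fractions:
                out.append(SampleID(None, d, 1, r, f))
    for i in range(1, design.n_blanks + 1):
        for f in fractions:
            out.append(SampleID(None, None, 1, i, f))
    return out


def design_to_dict(design: StudyDesign) -> dict:
    """Serializable form mirroring the product-catalog columns."""
    return {
        "products": [
            {
                "product_id": p.product_id,
                "chemical_form": p.chemical_form.value,
                "iron_dose_mg": p.iron_dose,
                "pharma_form": p.pharma_form.value,
                "product_type": p.product_type,
            }
            for p in design.products
        ],
        "diets": [d.value for d in design.diets],
        "n_batches": design.n_batches,
        "n_replicates": design.n_replicates,
        "n_blanks": design.n_blanks,
        "n_reference_reps": design.n_reference_reps,
        "fractions_per_digestion": design.fractions_per_digestion,
    }


def design_from_dict(data: dict) -> StudyDesign:
    products = [
        Product(
            product_id=int(row["product_id"]),
            chemical_form=ChemicalForm(row["chemical_form"]),
            iron_dose=float(row["iron_dose_mg"]),
            pharma_form=PharmaForm(row["pharma_form"]),
            product_type=row.get("product_type", "supplement"),
        )
        for row in data["products"]
    ]
    diets = [Diet(d) for d in data["diets"]]
    return StudyDesign(
        tuple(products), tuple(diets),
        n_batches=int(data.get("n_batches", 3)),
        n_replicates=int(data.get("n_replicates", 3)),
        n_blanks=int(data.get("n_blanks", 3)),
        n_reference_reps=int(data.get("n_reference_reps", 6)),
        fractions_per_digestion=int(data.get("fractions_per_digestion", 2)),
    )
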