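"""Reference classification of antimicrobial active ingredients.

Classes follow the usual veterinary-pharmacology grouping; WHO tiers follow
the WHO ranking of medically important antimicrobials (polymyxins,
quinolones and macrolides are critically important, highest priority;
aminoglycosides and penicillins are critically important, high priority;
first/second-generation cephalosporins, amphenicols, tetracyclines,
sulfonamides, diaminopyrimidines, lincosamides and pleuromutilins fall in
the lower tiers).  The pool covers the AAIs commonly found in oral
veterinary products for small-scale chicken production in the Mekong Delta;
methenamine — an antiseptic without a WHO/OIE class — is carried as
``unclassified`` rather than dropped.
"""

from __future__ import annotations

from .catalog import AAI, WhoTier

__all__ = ["DEFAULT_AAI_POOL", "default_classification"]

# name -> (class, WHO tier, OIE-listed)
_RAW: dict[str, tuple[str, WhoTier, bool]] = {
    # aminoglycosides (critically important, high priority)
    "neomycin": ("aminoglycoside", WhoTier.CRITICAL_HIGH, True),
    "gentamicin": ("aminoglycoside", WhoTier.CRITICAL_HIGH, True),
    "streptomycin": ("aminoglycoside", WhoTier.CRITICAL_HIGH, True),
    "spectinomycin": ("aminoglycoside", WhoTier.CRITICAL_HIGH, True),
    "apramycin": ("aminoglycoside", WhoTier.CRITICAL_HIGH, True),
    # amphenicols
    "florfenicol": ("amphenicol", WhoTier.OTHER, True),
    "thiamphenicol": ("amphenicol", WhoTier.OTHER, True),
    "chloramphenicol": ("amphenicol", WhoTier.OTHER, False),
    # 1st/2nd generation cephalosporins
    "cefadroxil": ("cephalosporin_1_2", WhoTier.OTHER, True),
    "cefotaxime": ("cephalosporin_1_2", WhoTier.CRITICAL_HIGHEST, False),
    "cefalexin": ("cephalosporin_1_2", WhoTier.OTHER, True),
    # diaminopyrimidines
    "trimethoprim": ("diaminopyrimidine", WhoTier.OTHER, True),
    # lincosamides
    "lincomycin": ("lincosamide", WhoTier.CRITICAL_HIGH, True),
    # macrolides (critically important, highest priority)
    "tylosin": ("macrolide", WhoTier.CRITICAL_HIGHEST, True),
    "tilmicosin": ("macrolide", WhoTier.CRITICAL_HIGHEST, True),
    "erythromycin": ("macrolide", WhoTier.CRITICAL_HIGHEST, True),
    "spiramycin": ("macrolide", WhoTier.CRITICAL_HIGHEST, True),
    "kitasamycin": ("macrolide", WhoTier.CRITICAL_HIGHEST, True),
    "josamycin": ("macrolide", WhoTier.CRITICAL_HIGHEST, True),
    # penicillins (critically important, high priority)
    "amoxicillin": ("penicillin", WhoTier.CRITICAL_HIGH, True),
    "ampicillin": ("penicillin", WhoTier.CRITICAL_HIGH, True),
    # pleuromutilins
    "tiamulin": ("pleuromutilin", WhoTier.OTHER, True),
    # polypeptides / polymyxins (colistin: highest priority)
    "colistin": ("polypeptide", WhoTier.CRITICAL_HIGHEST, True),
    "enramycin": ("polypeptide", WhoTier.OTHER, False),
    # quinolones / fluoroquinolones (critically important, highest priority)
    "enrofloxacin": ("quinolone", WhoTier.CRITICAL_HIGHEST, True),
    "flumequine": ("quinolone", WhoTier.CRITICAL_HIGHEST, True),
    "norfloxacin": ("quinolone", WhoTier.CRITICAL_HIGHEST, True),
    "ciprofloxacin": ("quinolone", WhoTier.CRITICAL_HIGHEST, False),
    "marbofloxacin": ("quinolone", WhoTier.CRITICAL_HIGHEST, False),
    # sulfonamides
    "sulphamethoxazole": ("sulfonamide", WhoTier.OTHER, True),
    "sulfadimidine": ("sulfonamide", WhoTier.OTHER, True),
    "sulfadimethoxine": ("sulfonamide", WhoTier.OTHER, True),
    "sulfaguanidine": ("sulfonamide", WhoTier.OTHER, False),
    "sulfadiazine": ("sulfonamide", WhoTier.OTHER, True),
    "sulfamethoxypyridazine": ("sulfonamide", WhoTier.OTHER, True),
    "sulfachloropyridazine": ("sulfonamide", WhoTier.OTHER, True),
    "sulfamethazine": ("sulfonamide", WhoTier.OTHER, True),
    "sulfathiazole": ("sulfonamide", WhoTier.OTHER, True),
    # tetracyclines
    "oxytetracycline": ("tetracycline", WhoTier.OTHER, True),
    "doxycycline": ("tetracycline", WhoTier.OTHER, True),
    "tetracycline": ("tetracycline", WhoTier.OTHER, True),
    # urinary antiseptic, outside the WHO/OIE antimicrobial classification
    "methenamine": ("unclassified", WhoTier.UNCLASSIFIED, False),
}


def default_classification() -> dict[str, AAI]:
    """The built-in AAI classification table, keyed by canonical name."""
    return {
        name: AAI(
            name=name,
            antimicrobial_class=cls,
            who_tier=tier,
            oie_listed=listed,
        )
        for name, (cls, tier, listed) in _RAW.items()
    }


DEFAULT_AAI_POOL: tuple[str, ...] = tuple(_RAW)
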