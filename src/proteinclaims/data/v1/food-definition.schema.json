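{
  "$defs": {
    "AminoAcidProfile": {
      "description": "Indispensable amino acid content of a protein source, mg per g protein.",
      "properties": {
        "content": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Content",
          "type": "object"
        }
      },
      "required": [
        "content"
      ],
      "title": "AminoAcidProfile",
      "type": "object"
    },
    "CombinationDeclaration": {
      "description": "Declares that this food is traditionally consumed with a companion.\n\nThe only combination rule in Canadian regulation is breakfast cereal with\n125 mL milk, under which the cereal's RDI switches (28 g -> 30 g); that\nswitched RDI is declared here as ``rdi_combined``.",
      "properties": {
        "companion_name": {
          "title": "Companion Name",
          "type": "string"
        },
        "rdi_combined": {
          "anyOf": [
            {
              "exclusiveMinimum": 0.0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Rdi Combined"
        }
      },
      "required": [
        "companion_name"
      ],
      "title": "CombinationDeclaration",
      "type": "object"
    },
    "Food": {
      "description": "A food product, its protein composition and serving bases.",
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "ingredients": {
          "default": [],
          "items": {
            "$ref": "#/$defs/IngredientProtein"
          },
          "title": "Ingredients",
          "type": "array"
        },
        "protein_per_100": {
          "minimum": 0.0,
          "title": "Protein Per 100",
          "type": "number"
        },
        "energy_per_serving": {
          "anyOf": [
            {
              "minimum": 0.0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Energy Per Serving"
        },
        "state": {
          "default": "solid",
          "enum": [
            "solid",
            "liquid"
          ],
          "title": "State",
          "type": "string"
        },
        "bases": {
          "$ref": "#/$defs/ServingBases"
        },
        "measured_per": {
          "anyOf": [
            {
              "minimum": 0.0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Measured Per"
        },
        "measured_pdcaas": {
          "anyOf": [
            {
              "maximum": 1.0,
              "minimum": 0.0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Measured Pdcaas"
        },
        "combination": {
          "anyOf": [
            {
              "$ref": "#/$defs/CombinationDeclaration"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        }
      },
      "required": [
        "name",
        "protein_per_100",
        "bases"
      ],
      "title": "Food",
      "type": "object"
    },
    "IngredientProtein": {
      "description": "One protein source within a food.\n\n``digestibility`` is true fecal nitrogen digestibility as a fraction in\n(0, 1]; ``protein_share`` is this ingredient's fraction of the food's\ntotal protein (shares across a food must sum to 1).",
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "profile": {
          "$ref": "#/$defs/AminoAcidProfile"
        },
        "digestibility": {
          "exclusiveMinimum": 0.0,
          "maximum": 1.0,
          "title": "Digestibility",
          "type": "number"
        },
        "protein_share": {
          "maximum": 1.0,
          "minimum": 0.0,
          "title": "Protein Share",
          "type": "number"
        }
      },
      "required": [
        "name",
        "profile",
        "digestibility",
        "protein_share"
      ],
      "title": "IngredientProtein",
      "type": "object"
    },
    "ServingBases": {
      "description": "Regulated serving bases, in g (solids) or mL (liquids).\n\n``rdi``: Canadian Reasonable Daily Intake; ``ra``: Canadian reference\namount; ``racc``: USA reference amount customarily consumed; ``serving``:\nlabel serving. At least one basis must be present.",
      "properties": {
        "rdi": {
          "anyOf": [
            {
              "exclusiveMinimum": 0.0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Rdi"
        },
        "ra": {
          "anyOf": [
            {
              "exclusiveMinimum": 0.0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ra"
        },
        "racc": {
          "anyOf": [
            {
              "exclusiveMinimum": 0.0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Racc"
        },
        "serving": {
          "anyOf": [
            {
              "exclusiveMinimum": 0.0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Serving"
        },
        "unit_kind": {
          "default": "mass-g",
          "enum": [
            "mass-g",
            "volume-mL"
          ],
          "title": "Unit Kind",
          "type": "string"
        }
      },
      "title": "ServingBases",
      "type": "object"
    }
  },
  "description": "Top-level structure of a JSON food-definition file.",
  "properties": {
    "schema_version": {
      "default": "1",
      "title": "Schema Version",
      "type": "string"
    },
    "foods": {
      "default": [],
      "items": {
        "$ref": "#/$defs/Food"
      },
      "title": "Foods",
      "type": "array"
    }
  },
  "title": "FoodDefinitionFile",
  "type": "object"
}
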