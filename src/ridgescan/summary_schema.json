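{
  "description": "Shape of summary.json (the shipped schema is generated from this model).",
  "properties": {
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "parameters": {
      "additionalProperties": true,
      "title": "Parameters",
      "type": "object"
    },
    "map": {
      "additionalProperties": true,
      "title": "Map",
      "type": "object"
    },
    "regions": {
      "additionalProperties": true,
      "title": "Regions",
      "type": "object"
    },
    "chromosomes": {
      "additionalProperties": true,
      "title": "Chromosomes",
      "type": "object"
    },
    "permutation": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Permutation"
    },
    "tissue_correlations": {
      "anyOf": [
        {
          "additionalProperties": {
            "type": "number"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Tissue Correlations"
    },
    "features": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Features"
    },
    "breaks": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Breaks"
    },
    "stages": {
      "items": {
        "type": "string"
      },
      "title": "Stages",
      "type": "array"
    }
  },
  "required": [
    "seed",
    "parameters",
    "map",
    "regions",
    "chromosomes",
    "stages"
  ],
  "title": "SummaryModel",
  "type": "object"
}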