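{
 "$defs": {
  "ConceptFilter": {
   "additionalProperties": false,
   "description": "Restrict a criterion to observations carrying one of several coded values.",
   "properties": {
    "kind": {
     "const": "concept",
     "title": "Kind",
     "type": "string"
    },
    "selectedConcepts": {
     "items": {
      "$ref": "#/$defs/TermCode"
     },
     "minItems": 1,
     "title": "Selectedconcepts",
     "type": "array"
    }
   },
   "required": [
    "kind",
    "selectedConcepts"
   ],
   "title": "ConceptFilter",
   "type": "object"
  },
  "Criterion": {
   "additionalProperties": false,
   "description": "One selectable concept, optionally value- and time-restricted.\n\n``termCodes`` lists alternative codes naming the same concept (e.g. the\nsame laboratory analyte in two code systems); a resource matching any of\nthem, or any hierarchical descendant, satisfies the criterion.",
   "properties": {
    "termCodes": {
     "items": {
      "$ref": "#/$defs/TermCode"
     },
     "minItems": 1,
     "title": "Termcodes",
     "type": "array"
    },
    "valueFilter": {
     "anyOf": [
      {
       "discriminator": {
        "mapping": {
         "concept": "#/$defs/ConceptFilter",
         "quantity-comparator": "#/$defs/QuantityComparatorFilter",
         "quantity-range": "#/$defs/QuantityRangeFilter"
        },
        "propertyName": "kind"
       },
       "oneOf": [
        {
         "$ref": "#/$defs/ConceptFilter"
        },
        {
         "$ref": "#/$defs/QuantityComparatorFilter"
        },
        {
         "$ref": "#/$defs/QuantityRangeFilter"
        }
       ]
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Valuefilter"
    },
    "timeRestriction": {
     "anyOf": [
      {
       "$ref": "#/$defs/TimeRestriction"
      },
      {
       "type": "null"
      }
     ],
     "default": null
    }
   },
   "required": [
    "termCodes"
   ],
   "title": "Criterion",
   "type": "object"
  },
  "QuantityComparatorFilter": {
   "additionalProperties": false,
   "description": "Restrict to measured values satisfying ``value <cmp> threshold`` in a UCUM unit.",
   "properties": {
    "kind": {
     "const": "quantity-comparator",
     "title": "Kind",
     "type": "string"
    },
    "comparator": {
     "enum": [
      "gt",
      "ge",
      "lt",
      "le",
      "eq"
     ],
     "title": "Comparator",
     "type": "string"
    },
    "value": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "pattern": "^(?!^[-+.]*$)[+-]?0*\\d*\\.?\\d*$",
       "type": "string"
      }
     ],
     "title": "Value"
    },
    "unit": {
     "minLength": 1,
     "title": "Unit",
     "type": "string"
    }
   },
   "required": [
    "kind",
    "comparator",
    "value",
    "unit"
   ],
   "title": "QuantityComparatorFilter",
   "type": "object"
  },
  "QuantityRangeFilter": {
   "additionalProperties": false,
   "description": "Restrict to measured values within an inclusive range in a UCUM unit.",
   "properties": {
    "kind": {
     "const": "quantity-range",
     "title": "Kind",
     "type": "string"
    },
    "minValue": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "pattern": "^(?!^[-+.]*$)[+-]?0*\\d*\\.?\\d*$",
       "type": "string"
      }
     ],
     "title": "Minvalue"
    },
    "maxValue": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "pattern": "^(?!^[-+.]*$)[+-]?0*\\d*\\.?\\d*$",
       "type": "string"
      }
     ],
     "title": "Maxvalue"
    },
    "unit": {
     "minLength": 1,
     "title": "Unit",
     "type": "string"
    }
   },
   "required": [
    "kind",
    "minValue",
    "maxValue",
    "unit"
   ],
   "title": "QuantityRangeFilter",
   "type": "object"
  },
  "TermCode": {
   "additionalProperties": false,
   "description": "A concept identifier: a code within a code system.\n\nEquality and hashing use ``(system, code)`` only; ``display`` is\nhuman-readable garnish and never participates in comparisons.",
   "properties": {
    "system": {
     "minLength": 1,
     "title": "System",
     "type": "string"
    },
    "code": {
     "minLength": 1,
     "title": "Code",
     "type": "string"
    },
    "display": {
     "default": "",
     "title": "Display",
     "type": "string"
    }
   },
   "required": [
    "system",
    "code"
   ],
   "title": "TermCode",
   "type": "object"
  },
  "TimeRestriction": {
   "additionalProperties": false,
   "description": "A calendar-date window; both bounds inclusive, at least one present.",
   "properties": {
    "afterDate": {
     "anyOf": [
      {
       "format": "date",
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Afterdate"
    },
    "beforeDate": {
     "anyOf": [
      {
       "format": "date",
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Beforedate"
    }
   },
   "title": "TimeRestriction",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "description": "A full feasibility query: CNF inclusion groups, DNF exclusion groups.",
 "properties": {
  "version": {
   "default": "feasquery-1",
   "title": "Version",
   "type": "string"
  },
  "inclusionCriteria": {
   "items": {
    "items": {
     "$ref": "#/$defs/Criterion"
    },
    "type": "array"
   },
   "minItems": 1,
   "title": "Inclusioncriteria",
   "type": "array"
  },
  "exclusionCriteria": {
   "items": {
    "items": {
     "$ref": "#/$defs/Criterion"
    },
    "type": "array"
   },
   "title": "Exclusioncriteria",
   "type": "array"
  }
 },
 "required": [
  "inclusionCriteria"
 ],
 "title": "Structured Query (feasquery dialect)",
 "type": "object",
 "$schema": "https://json-schema.org/draft/2020-12/schema"
}
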