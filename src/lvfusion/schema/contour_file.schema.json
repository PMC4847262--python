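{
 "$defs": {
  "ContourRecord": {
   "additionalProperties": true,
   "properties": {
    "phase": {
     "enum": [
      "ED",
      "ES"
     ],
     "title": "Phase",
     "type": "string"
    },
    "plane": {
     "$ref": "#/$defs/PlaneModel"
    },
    "points": {
     "items": {
      "items": {
       "type": "number"
      },
      "type": "array"
     },
     "minItems": 3,
     "title": "Points",
     "type": "array"
    },
    "surface": {
     "enum": [
      "endocardium",
      "epicardium"
     ],
     "title": "Surface",
     "type": "string"
    },
    "view": {
     "$ref": "#/$defs/ViewModel"
    }
   },
   "required": [
    "plane",
    "points",
    "surface",
    "phase",
    "view"
   ],
   "title": "ContourRecord",
   "type": "object"
  },
  "PlaneModel": {
   "additionalProperties": true,
   "properties": {
    "axis_u": {
     "items": {
      "type": "number"
     },
     "maxItems": 3,
     "minItems": 3,
     "title": "Axis U",
     "type": "array"
    },
    "axis_v": {
     "items": {
      "type": "number"
     },
     "maxItems": 3,
     "minItems": 3,
     "title": "Axis V",
     "type": "array"
    },
    "origin": {
     "items": {
      "type": "number"
     },
     "maxItems": 3,
     "minItems": 3,
     "title": "Origin",
     "type": "array"
    }
   },
   "required": [
    "origin",
    "axis_u",
    "axis_v"
   ],
   "title": "PlaneModel",
   "type": "object"
  },
  "ViewModel": {
   "additionalProperties": true,
   "properties": {
    "label": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Label"
    },
    "slice_index": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Slice Index"
    },
    "type": {
     "enum": [
      "SAX",
      "LAX"
     ],
     "title": "Type",
     "type": "string"
    }
   },
   "required": [
    "type"
   ],
   "title": "ViewModel",
   "type": "object"
  }
 },
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "additionalProperties": true,
 "properties": {
  "contours": {
   "items": {
    "$ref": "#/$defs/ContourRecord"
   },
   "title": "Contours",
   "type": "array"
  },
  "inter_slice_gap_mm": {
   "anyOf": [
    {
     "type": "number"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Inter Slice Gap Mm"
  },
  "schema_version": {
   "title": "Schema Version",
   "type": "string"
  },
  "slice_thickness_mm": {
   "anyOf": [
    {
     "type": "number"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Slice Thickness Mm"
  },
  "subject_id": {
   "title": "Subject Id",
   "type": "string"
  }
 },
 "required": [
  "schema_version",
  "subject_id",
  "contours"
 ],
 "title": "lvfusion contour interchange file",
 "type": "object"
}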