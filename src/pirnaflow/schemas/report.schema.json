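{
 "description": "Machine-readable pipeline report (one per run).",
 "properties": {
  "inputs": {
   "additionalProperties": {
    "type": "string"
   },
   "title": "Inputs",
   "type": "object"
  },
  "parameters": {
   "additionalProperties": {
    "anyOf": [
     {
      "type": "number"
     },
     {
      "type": "integer"
     },
     {
      "type": "string"
     }
    ]
   },
   "title": "Parameters",
   "type": "object"
  },
  "pirnaflow_version": {
   "title": "Pirnaflow Version",
   "type": "string"
  },
  "seed": {
   "title": "Seed",
   "type": "integer"
  },
  "stages": {
   "additionalProperties": {
    "additionalProperties": true,
    "type": "object"
   },
   "title": "Stages",
   "type": "object"
  }
 },
 "required": [
  "pirnaflow_version",
  "seed",
  "parameters",
  "inputs",
  "stages"
 ],
 "title": "Report",
 "type": "object"
}
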